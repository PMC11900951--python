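"""Exception hierarchy used across the package.

Every user-facing failure derives from :class:`PromwalkError` so that the
command-line layer can catch one type and exit with a single-line reason.
"""

from __future__ import annotations


class PromwalkError(Exception):
    """Base class for all promwalk failures."""


class ScoringError(PromwalkError):
    """A response vector cannot be scored (unknown item/code, all missing)."""


class UnknownItemError(ScoringError):
    """A response names an item that the instrument does not define."""


class UnknownCodeError(ScoringError):
    """A response code is not a defined option for its item."""


class MissingDataError(PromwalkError):
    """Required data are absent (all-missing visit, empty sample, ...)."""


class DegenerateDistributionError(PromwalkError):
    """A score distribution cannot be inverted (all values identical)."""


class SpearmanGateError(PromwalkError):
    """The Spearman correlation between paired scores is below the gate.

    Carries the computed coefficient so callers can report it.
    """

    def __init__(self, rho: float, threshold: float):
        self.rho = rho
        self.threshold = threshold
        super().__init__(
            f"Spearman rho {rho:.4f} is below the gate threshold "
            f"{threshold:g}; the crosswalk must not be built"
        )


class ScoreRangeError(PromwalkError):
    """A score lies outside the admissible instrument range."""


class ConfigError(PromwalkError):
    """A configuration value is invalid or internally inconsistent."""
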