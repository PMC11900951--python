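"""The four published linear-regression crosswalk equations.

These are the multi-directional mHHS ↔ HOOS / HOOS-12 conversions reported
by the derivation study (49 primary-THA patients, 121 matched visits):

    CWD mHHS    = 1.0713 · PD HOOS    + 2.6526
    CWD HOOS    = 0.7568 · PD mHHS    + 8.8474
    CWD mHHS    = 1.1124 · PD HOOS-12 − 3.1421
    CWD HOOS-12 = 0.728  · PD mHHS    + 13.192

Tabulated values are clamped to the target instrument range (e.g. the
HOOS-12 → mHHS line is negative at source 0 and clamps to 0).
"""

from __future__ import annotations

from .equating import CrosswalkTable, line_crosswalk
from .instruments import HOOS, HOOS12, MHHS, SCORE_RANGES

#: (source, target) → (slope, intercept) as printed, at full precision
PUBLISHED_EQUATIONS: dict[tuple[str, str], tuple[float, float]] = {
    (HOOS, MHHS): (1.0713, 2.6526),
    (MHHS, HOOS): (0.7568, 8.8474),
    (HOOS12, MHHS): (1.1124, -3.1421),
    (MHHS, HOOS12): (0.728, 13.192),
}

#: number of matched visits the published equations were derived from
PUBLISHED_N_PAIRS = 121


def published_crosswalk(source: str, target: str) -> CrosswalkTable:
    """One published LR conversion as a tabulated crosswalk."""
    key = (source, target)
    if key not in PUBLISHED_EQUATIONS:
        raise KeyError(
            f"no published equation for {source} -> {target}; "
            f"available: {sorted(PUBLISHED_EQUATIONS)}"
        )
    slope, intercept = PUBLISHED_EQUATIONS[key]
    return line_crosswalk(
        source,
        target,
        slope,
        intercept,
        SCORE_RANGES[source],
        SCORE_RANGES[target],
        n_pairs=PUBLISHED_N_PAIRS,
    )


def published_crosswalks() -> list[CrosswalkTable]:
    """All four published conversions, in the order printed above."""
    return [published_crosswalk(s, t) for (s, t) in PUBLISHED_EQUATIONS]
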