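"""Crosswalk validation: the Spearman gate, MAE reports and power analysis.

Crosswalk validity is quantified by the mean absolute error (MAE) of
crosswalk-derived (CWD) scores against the patient-derived (PD) scores of
the target instrument, overall, per follow-up time point and for the pain
and activity subcategories.  Crosswalk construction is gated on a Spearman
rank correlation of at least 0.3 between the two PD series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import instruments
from .equating import CrosswalkTable, MatchedPairSet, equipercentile_crosswalk
from .errors import (
    ConfigError,
    DegenerateDistributionError,
    MissingDataError,
    SpearmanGateError,
)
from .instruments import SUBCATEGORY_RANGES, TIMEPOINTS

DEFAULT_SPEARMAN_THRESHOLD = 0.3


@dataclass(frozen=True)
class PowerSpec:
    """Specification of the correlation power analysis.

    ``r_min`` is the smallest correlation worth detecting, tested at level
    ``alpha`` with target ``power``; ``sided`` is 1 or 2.
    """

    r_min: float = 0.3
    alpha: float = 0.05
    power: float = 0.8
    sided: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.r_min < 1.0:
            raise ConfigError(f"r_min must be in (0, 1), got {self.r_min}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ConfigError(f"power must be in (0, 1), got {self.power}")
        if self.sided not in (1, 2):
            raise ConfigError(f"sided must be 1 or 2, got {self.sided}")


@dataclass(frozen=True)
class ValidationReport:
    """MAE summary of one crosswalk direction against its matched pairs."""

    source: str
    target: str
    method: str
    spearman_r: float
    mae_overall: float
    mae_by_timepoint: Mapping[str, float]
    n_by_timepoint: Mapping[str, int]
    n_pairs: int
    max_abs_difference: float
    max_abs_at_source: float
    mae_subcategory: Mapping[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: rows Overall / per time point, one MAE column."""
        rows = [("Overall", self.mae_overall, self.n_pairs)]
        for tp in TIMEPOINTS:
            if tp in self.mae_by_timepoint:
                rows.append((tp, self.mae_by_timepoint[tp], self.n_by_timepoint[tp]))
            else:
                rows.append((tp, float("nan"), 0))
        return pd.DataFrame(rows, columns=["stratum", "mae", "n"])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise MissingDataError("Spearman correlation needs at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDistributionError(
            "a constant score series has no rank correlation"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_gate(
    pairs: MatchedPairSet, threshold: float = DEFAULT_SPEARMAN_THRESHOLD
) -> float:
    """Return Spearman rho of the matched pairs; fail the gate if below threshold.

    A correlation under the threshold means the two instruments do not
    measure the construct consistently enough for a crosswalk; the failure
    carries the computed coefficient.
    """
    rho = spearman_rho(pairs.x, pairs.y)
    if rho < threshold:
        raise SpearmanGateError(rho, threshold)
    return rho


def mae_report(
    pairs: MatchedPairSet,
    table: CrosswalkTable,
    *,
    stratify_by_timepoint: bool = True,
) -> ValidationReport:
    """MAE of CWD scores against PD target scores, pooled and per time point.

    The overall MAE pools all pairs (and therefore equals the count-weighted
    mean of the per-time-point MAEs).  Also reports the largest absolute
    CWD−PD difference and the source score at which it occurs.  Errors are
    computed on unrounded CWD values.
    """
    if table.source != pairs.instrument_x or table.target != pairs.instrument_y:
        raise ConfigError(
            f"table direction {table.source}->{table.target} does not match "
            f"pairs {pairs.instrument_x}->{pairs.instrument_y}"
        )
    cwd = np.asarray(table.apply(pairs.x), dtype=float)
    abs_err = np.abs(cwd - pairs.y)
    overall = float(abs_err.mean())
    i_max = int(np.argmax(abs_err))
    by_tp: dict[str, float] = {}
    n_tp: dict[str, int] = {}
    if stratify_by_timepoint:
        tp_series = pairs.pairs["timepoint"]
        for tp in TIMEPOINTS:
            mask = (tp_series == tp).to_numpy()
            if mask.any():
                by_tp[tp] = float(abs_err[mask].mean())
                n_tp[tp] = int(mask.sum())
    try:
        rho = spearman_rho(pairs.x, pairs.y)
    except (MissingDataError, DegenerateDistributionError):
        rho = float("nan")
    return ValidationReport(
        source=table.source,
        target=table.target,
        method=table.method,
        spearman_r=rho,
        mae_overall=overall,
        mae_by_timepoint=by_tp,
        n_by_timepoint=n_tp,
        n_pairs=len(pairs),
        max_abs_difference=float(abs_err[i_max]),
        max_abs_at_source=float(pairs.x[i_max]),
    )


def subcategory_pairs(
    responses: pd.DataFrame,
    source_instrument: str,
    target_instrument: str,
    subcategory: str,
) -> MatchedPairSet:
    """Matched pain or activity subcategory scores for one direction.

    Subcategory scores are computed per visit from the long-format response
    table (HOOS family rescaled to 0-100; mHHS raw out of 44 / 13) and
    inner-joined on patient-visit.
    """
    scored = {}
    for inst in (source_instrument, target_instrument):
        rows = []
        raw_inst = instruments.HOOS if inst == instruments.HOOS12 else inst
        sub = responses[responses["instrument"] == raw_inst]
        for (pid, tp), grp in sub.groupby(["patient_id", "timepoint"], sort=False):
            resp = {
                r.item_id: (None if pd.isna(r.code) else int(r.code))
                for r in grp.itertuples()
            }
            val = instruments.subcategory_scores(resp, inst)[subcategory]
            rows.append({"patient_id": pid, "timepoint": tp, "total": val})
        scored[inst] = pd.DataFrame(rows, columns=["patient_id", "timepoint", "total"])
    return MatchedPairSet.from_scores(
        scored[source_instrument],
        scored[target_instrument],
        source_instrument,
        target_instrument,
        SUBCATEGORY_RANGES[(source_instrument, subcategory)],
        SUBCATEGORY_RANGES[(target_instrument, subcategory)],
    )


def subcategory_mae(
    responses: pd.DataFrame,
    source_instrument: str,
    target_instrument: str,
) -> dict[str, float]:
    """Pain and activity subcategory MAEs for one crosswalk direction.

    Builds an equipercentile crosswalk per subcategory on the matched
    subcategory series (equipercentile only: both pain scales are graded,
    not continuous) and reports each MAE on the target's reported scale.
    """
    out: dict[str, float] = {}
    for sub in ("pain", "activity"):
        pairs = subcategory_pairs(
            responses, source_instrument, target_instrument, sub
        )
        table = equipercentile_crosswalk(pairs)
        out[sub] = mae_report(pairs, table, stratify_by_timepoint=False).mae_overall
    return out


# ---------------------------------------------------------------------------
# Correlation power analysis
# ---------------------------------------------------------------------------

def correlation_power(n: int, spec: PowerSpec) -> float:
    """Power of the n-pair test of rho = 0 against rho = r_min.

    Uses the t-based critical correlation at the chosen level together with
    the bias-corrected Fisher-z normal approximation
    zr = atanh(r) + r / (2(n − 1)).
    """
    if n < 4:
        raise ConfigError("correlation power analysis needs n >= 4")
    df = n - 2
    level = spec.alpha / spec.sided
    tcrit = stats.t.ppf(1.0 - level, df)
    r_crit = math.sqrt(tcrit**2 / (tcrit**2 + df))
    z_crit = math.atanh(r_crit)
    z_r = math.atanh(spec.r_min) + spec.r_min / (2.0 * (n - 1))
    scale = math.sqrt(n - 3)
    power = stats.norm.cdf((z_r - z_crit) * scale)
    if spec.sided == 2:
        power += stats.norm.cdf((-z_r - z_crit) * scale)
    return float(power)


def required_sample_size(spec: PowerSpec = PowerSpec(), n_max: int = 10**6) -> int:
    """Smallest number of matched pairs reaching the target power.

    Power is monotone increasing in n, so the smallest n with
    ``correlation_power(n) >= spec.power`` is found by bisection over
    [4, n_max].
    """
    lo, hi = 4, 4
    if correlation_power(lo, spec) >= spec.power:
        return lo
    while correlation_power(hi, spec) < spec.power:
        hi *= 2
        if hi > n_max:
            raise ConfigError(
                f"required sample size exceeds {n_max}; is r_min too small?"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if correlation_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
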