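"""Observed-score equating between two matched PD score series.

Two linking methods are provided:

* **Equipercentile (EQ)** — non-parametric observed-score equating.  Each
  side's empirical distribution is summarised by the mid-percentile rank of
  its distinct observed scores, continuized by linear interpolation between
  consecutive distinct scores (and anchored to the instrument range
  endpoints, since bounded instruments forbid open-ended extrapolation).
  A source score s maps to the target score whose percentile rank equals
  the source percentile rank of s.
* **Linear regression (LR)** — ordinary least squares of target on source;
  the fitted line is tabulated over the integer source grid and clamped to
  the target range.

Both methods produce a :class:`CrosswalkTable` covering every integer
source score over the full instrument range, guaranteed monotone
non-decreasing and range-safe.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDistributionError,
    MissingDataError,
    ScoreRangeError,
)

Direction = Literal["x_to_y", "y_to_x"]


def round_half_away(x):
    """Round half away from zero (presentation/export rounding)."""
    x = np.asarray(x, dtype=float)
    out = np.copysign(np.floor(np.abs(x) + 0.5), x)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MatchedPairSet:
    """Paired PD scores of two instruments at common patient-visits.

    ``pairs`` has columns ``patient_id, timepoint, score_x, score_y``; one
    row per matched visit, no duplicates, both scores present and within
    their instruments' ranges.
    """

    pairs: pd.DataFrame
    instrument_x: str
    instrument_y: str
    range_x: tuple[float, float]
    range_y: tuple[float, float]

    def __post_init__(self) -> None:
        df = self.pairs
        required = {"patient_id", "timepoint", "score_x", "score_y"}
        if not required.issubset(df.columns):
            raise ValueError(f"pairs must have columns {sorted(required)}")
        if df.duplicated(["patient_id", "timepoint"]).any():
            raise ValueError("duplicate (patient_id, timepoint) in matched pairs")
        for col, (lo, hi) in (("score_x", self.range_x), ("score_y", self.range_y)):
            s = df[col]
            if s.isna().any():
                raise ValueError(f"{col} contains missing values")
            if ((s < lo) | (s > hi)).any():
                raise ValueError(f"{col} outside [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def x(self) -> np.ndarray:
        return self.pairs["score_x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.pairs["score_y"].to_numpy(dtype=float)

    def swapped(self) -> "MatchedPairSet":
        """The same pairs with the roles of x and y exchanged."""
        df = self.pairs.rename(
            columns={"score_x": "score_y", "score_y": "score_x"}
        )[["patient_id", "timepoint", "score_x", "score_y"]]
        return MatchedPairSet(
            df, self.instrument_y, self.instrument_x, self.range_y, self.range_x
        )

    @classmethod
    def from_scores(
        cls,
        scores_x: pd.DataFrame,
        scores_y: pd.DataFrame,
        instrument_x: str,
        instrument_y: str,
        range_x: tuple[float, float],
        range_y: tuple[float, float],
        value_col: str = "total",
    ) -> "MatchedPairSet":
        """Inner-join two per-visit score tables on (patient_id, timepoint)."""
        keys = ["patient_id", "timepoint"]
        left = scores_x[keys + [value_col]].rename(columns={value_col: "score_x"})
        right = scores_y[keys + [value_col]].rename(columns={value_col: "score_y"})
        df = left.merge(right, on=keys, how="inner").dropna(
            subset=["score_x", "score_y"]
        )
        df = df.reset_index(drop=True)
        if df.empty:
            raise MissingDataError(
                f"no matched {instrument_x}/{instrument_y} visits"
            )
        return cls(df, instrument_x, instrument_y, range_x, range_y)


@dataclass(frozen=True)
class PercentileRankFunction:
    """Continuized mid-percentile-rank function of one score sample.

    At each distinct observed score s the rank is the mid-percentile rank
    100·(#below + 0.5·#equal)/n; between distinct observed scores the rank
    is linearly interpolated, and the instrument range endpoints (offset by
    half a score unit) anchor ranks 0 and 100.
    """

    support: np.ndarray          # sorted distinct observed scores
    frequencies: np.ndarray
    n: int
    score_range: tuple[float, float]
    _nodes_x: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _nodes_r: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @classmethod
    def from_sample(
        cls,
        sample: Iterable[float],
        score_range: tuple[float, float] | None = None,
    ) -> "PercentileRankFunction":
        arr = np.asarray(list(sample), dtype=float)
        if arr.size == 0:
            raise MissingDataError("cannot build a percentile-rank function from an empty sample")
        support, freq = np.unique(arr, return_counts=True)
        n = int(arr.size)
        if score_range is None:
            score_range = (float(support[0]), float(support[-1]))
        lo, hi = score_range
        if support[0] < lo or support[-1] > hi:
            raise ScoreRangeError(
                f"observed scores fall outside the declared range [{lo}, {hi}]"
            )
        below = np.concatenate(([0.0], np.cumsum(freq)[:-1]))
        ranks = 100.0 * (below + 0.5 * freq) / n
        nodes_x = np.concatenate(([lo - 0.5], support, [hi + 0.5]))
        nodes_r = np.concatenate(([0.0], ranks, [100.0]))
        obj = cls(support, freq, n, (lo, hi))
        object.__setattr__(obj, "_nodes_x", nodes_x)
        object.__setattr__(obj, "_nodes_r", nodes_r)
        return obj

    def forward(self, x):
        """Percentile rank of score(s) ``x`` in (0, 100)."""
        return np.interp(x, self._nodes_x, self._nodes_r)

    def inverse(self, r):
        """Score at percentile rank(s) ``r``, clamped to the score range."""
        s = np.interp(r, self._nodes_r, self._nodes_x)
        return np.clip(s, self.score_range[0], self.score_range[1])


def percentile_rank(sample: Iterable[float], x: float) -> float:
    """Mid-percentile rank of ``x`` within ``sample``, in (0, 100).

    For x equal to an observed value this is 100·(#below + 0.5·#equal)/n;
    between observed values ranks are linearly continuized.
    """
    return float(PercentileRankFunction.from_sample(sample).forward(x))


@dataclass(frozen=True)
class CrosswalkTable:
    """A monotone integer-grid mapping from a source to a target score.

    Applying the table yields crosswalk-derived (CWD) scores.  ``entries``
    cover every integer source score over the full source range;
    ``fit_meta`` carries slope/intercept for LR tables.
    """

    method: str                        # "EQ" or "LR"
    source: str
    target: str
    source_range: tuple[float, float]
    target_range: tuple[float, float]
    grid: np.ndarray                   # integer source scores
    targets: np.ndarray                # exact target values
    n_pairs: int = 0
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.source_range
        expect = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
        if not np.array_equal(self.grid, expect):
            raise ValueError("grid must cover every integer source score in range")
        if np.any(np.diff(self.targets) < -1e-9):
            raise ValueError("crosswalk targets must be non-decreasing")
        tlo, thi = self.target_range
        if self.targets.min() < tlo - 1e-9 or self.targets.max() > thi + 1e-9:
            raise ValueError("crosswalk targets outside the target range")

    @property
    def targets_rounded(self) -> np.ndarray:
        return round_half_away(self.targets)

    def apply(self, score) -> float | np.ndarray:
        """Convert PD score(s) to CWD score(s).

        Integer scores are table lookups; non-integer scores interpolate
        linearly between adjacent grid entries.  Out-of-range input is
        rejected naming the admissible range.
        """
        arr = np.asarray(score, dtype=float)
        lo, hi = self.source_range
        if np.any(arr < lo) or np.any(arr > hi):
            raise ScoreRangeError(
                f"score outside the admissible {self.source} range [{lo:g}, {hi:g}]"
            )
        out = np.interp(arr, self.grid, self.targets)
        if out.ndim == 0:
            return float(out)
        return out

    # -- plain-text serialisation -------------------------------------

    def to_csv(self, path) -> None:
        """Write the table as CSV with ``#`` header comment lines."""
        lines = [
            f"# method: {self.method}",
            f"# source: {self.source}",
            f"# target: {self.target}",
            f"# source_range: {self.source_range[0]:g},{self.source_range[1]:g}",
            f"# target_range: {self.target_range[0]:g},{self.target_range[1]:g}",
            f"# n_pairs: {self.n_pairs}",
        ]
        for k, v in self.fit_meta.items():
            lines.append(f"# {k}: {v!r}")
        body = pd.DataFrame(
            {
                "source_score": self.grid,
                "target_score_exact": self.targets,
                "target_score_rounded": self.targets_rounded.astype(int),
            }
        )
        buf = _io.StringIO()
        body.to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n" + buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "CrosswalkTable":
        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            text = fh.readlines()
        body_start = 0
        for i, line in enumerate(text):
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        df = pd.read_csv(_io.StringIO("".join(text[body_start:])))
        fit_meta = {}
        for k in ("slope", "intercept"):
            if k in meta:
                fit_meta[k] = float(meta[k])
        srange = tuple(float(v) for v in meta["source_range"].split(","))
        trange = tuple(float(v) for v in meta["target_range"].split(","))
        return cls(
            method=meta["method"],
            source=meta["source"],
            target=meta["target"],
            source_range=srange,  # type: ignore[arg-type]
            target_range=trange,  # type: ignore[arg-type]
            grid=df["source_score"].to_numpy(),
            targets=df["target_score_exact"].to_numpy(dtype=float),
            n_pairs=int(meta.get("n_pairs", 0)),
            fit_meta=fit_meta,
        )


def _oriented(pairs: MatchedPairSet, direction: Direction) -> MatchedPairSet:
    if direction == "x_to_y":
        return pairs
    if direction == "y_to_x":
        return pairs.swapped()
    raise ValueError(f"direction must be 'x_to_y' or 'y_to_x', got {direction!r}")


def _integer_grid(score_range: tuple[float, float]) -> np.ndarray:
    lo, hi = score_range
    return np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)


def equipercentile_crosswalk(
    pairs: MatchedPairSet, direction: Direction = "x_to_y"
) -> CrosswalkTable:
    """Build an equipercentile crosswalk from matched PD score pairs.

    Scores with the same (continuized) percentile rank in the two marginal
    distributions are considered equivalent: for every integer source score
    s, the table entry is the target score at the source percentile rank of
    s, interpolating linearly between observed target scores and clamping
    to the target range.
    """
    p = _oriented(pairs, direction)
    for name, arr in ((p.instrument_x, p.x), (p.instrument_y, p.y)):
        if np.unique(arr).size < 2:
            raise DegenerateDistributionError(
                f"all {name} scores are identical; the score distribution "
                "cannot be inverted for equipercentile equating"
            )
    f_src = PercentileRankFunction.from_sample(p.x, p.range_x)
    f_tgt = PercentileRankFunction.from_sample(p.y, p.range_y)
    grid = _integer_grid(p.range_x)
    targets = np.asarray(f_tgt.inverse(f_src.forward(grid)), dtype=float)
    targets = np.maximum.accumulate(targets)  # guard against float wobble
    return CrosswalkTable(
        method="EQ",
        source=p.instrument_x,
        target=p.instrument_y,
        source_range=p.range_x,
        target_range=p.range_y,
        grid=grid,
        targets=targets,
        n_pairs=len(p),
    )


def linear_regression_crosswalk(
    pairs: MatchedPairSet, direction: Direction = "x_to_y"
) -> CrosswalkTable:
    """Build a linear-regression crosswalk from matched PD score pairs.

    Ordinary least squares of target on source; the fitted line is
    tabulated over the integer source grid and clamped to the target range.
    Slope and intercept are recorded at full precision in ``fit_meta``.
    """
    p = _oriented(pairs, direction)
    if np.unique(p.x).size < 2:
        raise DegenerateDistributionError(
            f"zero variance in {p.instrument_x} scores; no regression line exists"
        )
    fit = stats.linregress(p.x, p.y)
    grid = _integer_grid(p.range_x)
    line = fit.slope * grid + fit.intercept
    targets = np.clip(line, p.range_y[0], p.range_y[1])
    if fit.slope < 0:
        # a decreasing line is a valid OLS fit but not a valid crosswalk
        raise DegenerateDistributionError(
            "fitted slope is negative; the score relationship is not monotone increasing"
        )
    return CrosswalkTable(
        method="LR",
        source=p.instrument_x,
        target=p.instrument_y,
        source_range=p.range_x,
        target_range=p.range_y,
        grid=grid,
        targets=targets,
        n_pairs=len(p),
        fit_meta={
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "stderr": float(fit.stderr),
            "intercept_stderr": float(fit.intercept_stderr),
        },
    )


def apply_crosswalk(table: CrosswalkTable, score) -> float | np.ndarray:
    """Convert PD score(s) through ``table`` (see :meth:`CrosswalkTable.apply`)."""
    return table.apply(score)


def line_crosswalk(
    source: str,
    target: str,
    slope: float,
    intercept: float,
    source_range: tuple[float, float],
    target_range: tuple[float, float],
    n_pairs: int = 0,
) -> CrosswalkTable:
    """Tabulate a fixed linear equation as an LR crosswalk table."""
    grid = _integer_grid(source_range)
    targets = np.clip(slope * grid + intercept, target_range[0], target_range[1])
    return CrosswalkTable(
        method="LR",
        source=source,
        target=target,
        source_range=source_range,
        target_range=target_range,
        grid=grid,
        targets=targets,
        n_pairs=n_pairs,
        fit_meta={"slope": float(slope), "intercept": float(intercept)},
    )
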