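"""Reading and writing the package's plain-text formats.

* long-format responses CSV: ``patient_id,timepoint,instrument,item_id,code``
  (empty cell = missing answer);
* per-visit scores CSV: one row per patient-visit-instrument with the
  total, subscale columns and missing-item count;
* run configuration as ``key = value`` lines (``#`` comments allowed).

All files are RFC-4180 CSV, UTF-8, dot decimal.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import instruments
from .errors import PromwalkError, UnknownItemError
from .instruments import (
    HOOS,
    HOOS12,
    MHHS,
    SCORE_RANGES,
    TIMEPOINTS,
    ScoreRecord,
)

RESPONSE_COLUMNS = ["patient_id", "timepoint", "instrument", "item_id", "code"]

#: union of subscale column names across the three instruments
SCORE_COLUMNS = [
    "patient_id",
    "timepoint",
    "instrument",
    "total",
    "pain",
    "gait",
    "activity",
    "symptoms",
    "adl",
    "sport",
    "qol",
    "function",
    "n_missing_items",
]


def read_responses(path) -> pd.DataFrame:
    """Read and validate a long-format item-response CSV.

    Raises with the offending line number for unknown instruments,
    time points, items or codes.
    """
    df = pd.read_csv(
        path, dtype={"patient_id": str, "timepoint": str, "instrument": str, "item_id": str}
    )
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise PromwalkError(f"responses file is missing columns {missing}")
    df = df[RESPONSE_COLUMNS]
    item_maps = {
        MHHS: instruments.load_instrument(MHHS).item_map,
        HOOS: instruments.load_instrument(HOOS).item_map,
    }
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        if row.timepoint not in TIMEPOINTS:
            raise PromwalkError(
                f"line {line}: unknown timepoint {row.timepoint!r} "
                f"(expected one of {list(TIMEPOINTS)})"
            )
        if row.instrument not in item_maps:
            raise PromwalkError(
                f"line {line}: unknown instrument {row.instrument!r} "
                f"(expected one of {sorted(item_maps)})"
            )
        item = item_maps[row.instrument].get(row.item_id)
        if item is None:
            raise UnknownItemError(
                f"line {line}: item {row.item_id!r} is not defined for {row.instrument}"
            )
        if not pd.isna(row.code):
            try:
                item.points_for(int(row.code))
            except PromwalkError as exc:
                raise PromwalkError(f"line {line}: {exc}") from exc
    return df


def iter_visits(responses: pd.DataFrame):
    """Yield (patient_id, timepoint, instrument, {item_id: code}) per visit."""
    for (pid, tp, inst), grp in responses.groupby(
        ["patient_id", "timepoint", "instrument"], sort=False
    ):
        resp = {
            r.item_id: (None if pd.isna(r.code) else int(r.code))
            for r in grp.itertuples()
        }
        yield pid, tp, inst, resp


def _record_to_row(rec: ScoreRecord) -> dict:
    row = {c: None for c in SCORE_COLUMNS}
    row.update(
        patient_id=rec.patient_id,
        timepoint=rec.timepoint,
        instrument=rec.instrument,
        total=rec.total,
        n_missing_items=rec.n_missing_items,
    )
    for name, val in rec.subscale_scores.items():
        row[name] = val
    return row


def score_responses(responses: pd.DataFrame, *, include_hoos12: bool = True) -> pd.DataFrame:
    """Score every visit in a validated response table.

    Returns one row per patient-visit-instrument; HOOS visits additionally
    yield an extracted HOOS-12 row when ``include_hoos12`` is set.
    """
    rows = []
    for pid, tp, inst, resp in iter_visits(responses):
        rec = instruments.score_visit(resp, inst, patient_id=pid, timepoint=tp)
        rows.append(_record_to_row(rec))
        if inst == HOOS and include_hoos12:
            rec12 = instruments.extract_hoos12(resp, patient_id=pid, timepoint=tp)
            rows.append(_record_to_row(rec12))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"patient_id": str, "timepoint": str, "instrument": str}
    )


def matched_pairs_from_scores(
    scores: pd.DataFrame, source: str, target: str
):
    """Build a total-score MatchedPairSet for one direction from a score table."""
    from .equating import MatchedPairSet

    sub = {
        inst: scores[scores["instrument"] == inst].dropna(subset=["total"])
        for inst in (source, target)
    }
    return MatchedPairSet.from_scores(
        sub[source],
        sub[target],
        source,
        target,
        SCORE_RANGES[source],
        SCORE_RANGES[target],
    )


def read_config(path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PromwalkError(f"config line {i}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
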