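"""Instrument definitions and patient-derived (PD) score computation.

Implements the three hip instruments used throughout the package:

* **mHHS** — the modified Harris Hip Score, the self-reported part of the
  Harris Hip Score with the clinician domains and the public-transport item
  removed.  Weighted items; total on 0-90, higher = better.
* **HOOS** — the Hip disability and Osteoarthritis Outcome Score: 40 items
  (codes 0 best … 4 worst) in five subscales (pain, symptoms, activities of
  daily living, sport, quality of life), each transformed to 0-100
  (100 = best).  The overall score used here is the unweighted mean of the
  five subscale scores.
* **HOOS-12** — the 12-item short form extracted from a completed HOOS
  (pain, function, quality-of-life scales of four items each), scored like
  HOOS subscales; total is the mean of the three scale scores.

Rubrics are bundled as plain-text CSV files under ``promwalk/rubrics`` and
can be edited without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import (
    MissingDataError,
    ScoringError,
    UnknownCodeError,
    UnknownItemError,
)

MHHS = "mHHS"
HOOS = "HOOS"
HOOS12 = "HOOS-12"

INSTRUMENTS = (MHHS, HOOS, HOOS12)
TIMEPOINTS = ("preop", "3m", "6m", "12m")

#: score range of each instrument total
SCORE_RANGES: dict[str, tuple[float, float]] = {
    MHHS: (0.0, 90.0),
    HOOS: (0.0, 100.0),
    HOOS12: (0.0, 100.0),
}

#: range of each pain/activity subcategory series as reported (mHHS raw,
#: HOOS family rescaled to 0-100)
SUBCATEGORY_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    (MHHS, "pain"): (0.0, 44.0),
    (MHHS, "activity"): (0.0, 13.0),
    (HOOS, "pain"): (0.0, 100.0),
    (HOOS, "activity"): (0.0, 100.0),
    (HOOS12, "pain"): (0.0, 100.0),
    (HOOS12, "activity"): (0.0, 100.0),
}

_HOOS_SUBSCALE_BY_DOMAIN = {
    "pain": "pain",
    "symptoms": "symptoms",
    "activities": "adl",
    "sport": "sport",
    "qol": "qol",
}

_MHHS_SUBSCALE_BY_DOMAIN = {
    "pain": "pain",
    "gait": "gait",
    "activities": "activity",
}


@dataclass(frozen=True)
class ItemDefinition:
    """One question: its domain, ordered response options and weights."""

    item_id: str
    domain: str
    options: tuple[tuple[int, float], ...]  # (code, points), ordered by code
    retained: bool = True

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.options]
        if codes != sorted(set(codes)):
            raise ValueError(f"{self.item_id}: option codes must be strictly increasing")
        if any(p < 0 for _, p in self.options):
            raise ValueError(f"{self.item_id}: negative point value")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.options)

    @property
    def max_points(self) -> float:
        return max(p for _, p in self.options)

    def points_for(self, code: int) -> float:
        for c, p in self.options:
            if c == code:
                return p
        raise UnknownCodeError(
            f"code {code!r} is not a defined option for item {self.item_id!r} "
            f"(defined: {list(self.codes)})"
        )


@dataclass(frozen=True)
class InstrumentDefinition:
    """An instrument: its items, score range and named subscales."""

    name: str
    items: tuple[ItemDefinition, ...]
    score_min: float
    score_max: float
    subscales: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.name}: duplicate item ids")

    @property
    def item_map(self) -> dict[str, ItemDefinition]:
        return {it.item_id: it for it in self.items}

    @property
    def retained_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.retained)

    def max_points(self, retained_only: bool = True) -> float:
        """Sum of best-option points over items (optionally all items)."""
        items = self.retained_items if retained_only else self.items
        return sum(it.max_points for it in items)


@dataclass(frozen=True)
class ItemResponse:
    """One row of the long-format input: a single answered (or blank) item."""

    patient_id: str
    timepoint: str
    instrument: str
    item_id: str
    code: int | None


@dataclass(frozen=True)
class ScoreRecord:
    """A patient-derived (PD) total plus subscale scores for one visit."""

    patient_id: str
    timepoint: str
    instrument: str
    total: float | None
    subscale_scores: Mapping[str, float | None]
    n_missing_items: int = 0


def _rubric_path(filename: str):
    return resources.files("promwalk.rubrics").joinpath(filename)


@lru_cache(maxsize=None)
def load_instrument(name: str) -> InstrumentDefinition:
    """Load an instrument definition from its bundled rubric file.

    Parameters
    ----------
    name:
        ``"mHHS"`` or ``"HOOS"``.  (HOOS-12 has no rubric of its own; it is
        extracted from HOOS via :func:`load_hoos12_map`.)
    """
    if name == MHHS:
        fn, lo, hi, sub_by_domain = "mhhs.csv", 0.0, 90.0, _MHHS_SUBSCALE_BY_DOMAIN
    elif name == HOOS:
        fn, lo, hi, sub_by_domain = "hoos.csv", 0.0, 100.0, _HOOS_SUBSCALE_BY_DOMAIN
    else:
        raise UnknownItemError(f"no rubric for instrument {name!r}")
    with resources.as_file(_rubric_path(fn)) as p:
        df = pd.read_csv(p, comment="#")
    items: list[ItemDefinition] = []
    for (item_id, domain, retained), grp in df.groupby(
        ["item_id", "domain", "retained"], sort=False
    ):
        opts = tuple(
            (int(r.code), float(r.points))
            for r in grp.sort_values("code").itertuples()
        )
        items.append(ItemDefinition(str(item_id), str(domain), opts, bool(retained)))
    subscales: dict[str, tuple[str, ...]] = {}
    for sub in sub_by_domain.values():
        subscales[sub] = tuple(
            it.item_id
            for it in items
            if it.retained and sub_by_domain[it.domain] == sub
        )
    inst = InstrumentDefinition(name, tuple(items), lo, hi, subscales)
    if name == MHHS and inst.max_points() != 90.0:
        raise ValueError("mHHS rubric does not sum to 90 over retained items")
    return inst


@lru_cache(maxsize=None)
def load_hoos12_map() -> dict[str, tuple[str, ...]]:
    """HOOS-12 scale → contributing HOOS item ids (bundled mapping table)."""
    with resources.as_file(_rubric_path("hoos12.csv")) as p:
        df = pd.read_csv(p, comment="#")
    out: dict[str, tuple[str, ...]] = {}
    for scale, grp in df.groupby("scale", sort=False):
        out[str(scale)] = tuple(grp["item_id"])
    hoos_items = set(load_instrument(HOOS).item_map)
    stray = [i for ids in out.values() for i in ids if i not in hoos_items]
    if stray:
        raise ValueError(f"HOOS-12 map references unknown HOOS items: {stray}")
    return out


def _validate_codes(responses: Mapping[str, int | None], inst: InstrumentDefinition) -> None:
    item_map = inst.item_map
    for item_id, code in responses.items():
        if item_id not in item_map:
            raise UnknownItemError(
                f"item {item_id!r} is not defined for {inst.name}"
            )
        if code is not None:
            item_map[item_id].points_for(int(code))  # raises UnknownCodeError


def score_mhhs(
    responses: Mapping[str, int | None],
    *,
    patient_id: str = "",
    timepoint: str = "",
) -> ScoreRecord:
    """Score one mHHS visit from an item_id → code mapping.

    The total is the sum of option points over retained items (the
    public-transport item never contributes).  Because item weights are
    unequal, any missing retained item makes the visit total missing; an
    all-missing visit is rejected outright.

    Subscale scores are raw point sums: pain (out of 44), gait (out of 33)
    and activity = stairs + shoes/socks + sitting (out of 13).
    """
    inst = load_instrument(MHHS)
    _validate_codes(responses, inst)
    answered: dict[str, float] = {}
    n_missing = 0
    for it in inst.retained_items:
        code = responses.get(it.item_id)
        if code is None:
            n_missing += 1
        else:
            answered[it.item_id] = it.points_for(int(code))
    if not answered:
        raise MissingDataError(
            f"mHHS visit ({patient_id!r}, {timepoint!r}): every retained item is missing"
        )
    if n_missing:
        total = None
        subscales = {name: None for name in inst.subscales}
    else:
        total = sum(answered.values())
        subscales = {
            name: sum(answered[i] for i in ids)
            for name, ids in inst.subscales.items()
        }
    return ScoreRecord(patient_id, timepoint, MHHS, total, subscales, n_missing)


def _scale_0_100(codes: list[int]) -> float:
    # codes run 0 (best) .. 4 (worst); transform to 0-100 with 100 = best
    return 100.0 - (sum(codes) / len(codes)) / 4.0 * 100.0


def _score_item_group(
    responses: Mapping[str, int | None], item_ids: tuple[str, ...]
) -> float | None:
    """Mean-based 0-100 score of an item group; missing if under half answered."""
    codes = [
        int(responses[i])
        for i in item_ids
        if i in responses and responses[i] is not None
    ]
    if 2 * len(codes) < len(item_ids):
        return None
    return _scale_0_100(codes)


def score_hoos_subscale(responses: Mapping[str, int | None], subscale: str) -> float | None:
    """Score one HOOS subscale on the 0-100 scale (100 = best).

    Follows the instrument's customary missing-data rule: the subscale is
    computed from the mean of answered items if at least half of its items
    are answered, otherwise it is missing (``None``), never zero.
    """
    inst = load_instrument(HOOS)
    if subscale not in inst.subscales:
        raise UnknownItemError(
            f"unknown HOOS subscale {subscale!r} (defined: {sorted(inst.subscales)})"
        )
    _validate_codes(responses, inst)
    return _score_item_group(responses, inst.subscales[subscale])


def score_hoos_total(
    responses: Mapping[str, int | None],
    *,
    patient_id: str = "",
    timepoint: str = "",
) -> ScoreRecord:
    """Score one HOOS visit: five subscales plus their unweighted mean."""
    inst = load_instrument(HOOS)
    _validate_codes(responses, inst)
    if not any(v is not None for v in responses.values()):
        raise MissingDataError(
            f"HOOS visit ({patient_id!r}, {timepoint!r}): every item is missing"
        )
    subscales = {
        name: _score_item_group(responses, ids)
        for name, ids in inst.subscales.items()
    }
    n_missing = sum(
        1
        for it in inst.items
        if responses.get(it.item_id) is None
    )
    if any(v is None for v in subscales.values()):
        total = None
    else:
        total = sum(subscales.values()) / len(subscales)  # type: ignore[arg-type]
    return ScoreRecord(patient_id, timepoint, HOOS, total, subscales, n_missing)


def extract_hoos12(
    responses: Mapping[str, int | None],
    *,
    patient_id: str = "",
    timepoint: str = "",
) -> ScoreRecord:
    """Extract and score the HOOS-12 short form from a completed HOOS visit.

    Three four-item scales (pain, function, qol) are each scored on 0-100
    like HOOS subscales; the total is their unweighted mean.
    """
    inst = load_instrument(HOOS)
    _validate_codes(responses, inst)
    h12 = load_hoos12_map()
    scales = {name: _score_item_group(responses, ids) for name, ids in h12.items()}
    n_missing = sum(
        1
        for ids in h12.values()
        for i in ids
        if responses.get(i) is None
    )
    if all(responses.get(i) is None for ids in h12.values() for i in ids):
        raise MissingDataError(
            f"HOOS-12 visit ({patient_id!r}, {timepoint!r}): every designated item is missing"
        )
    if any(v is None for v in scales.values()):
        total = None
    else:
        total = sum(scales.values()) / len(scales)  # type: ignore[arg-type]
    return ScoreRecord(patient_id, timepoint, HOOS12, total, scales, n_missing)


def subcategory_scores(
    responses: Mapping[str, int | None], instrument: str
) -> dict[str, float | None]:
    """Pain and activity subcategory scores, on each instrument's reported scale.

    HOOS and HOOS-12 subcategories are rescaled to 0-100 (100 = best);
    mHHS pain is the raw pain points (out of 44) and mHHS activity the raw
    stairs + shoes/socks + sitting points (out of 13).  A subcategory with
    missing constituent items is ``None``.
    """
    if instrument == MHHS:
        inst = load_instrument(MHHS)
        _validate_codes(responses, inst)
        out: dict[str, float | None] = {}
        for sub in ("pain", "activity"):
            ids = inst.subscales[sub]
            if any(responses.get(i) is None for i in ids):
                out[sub] = None
            else:
                out[sub] = sum(
                    inst.item_map[i].points_for(int(responses[i])) for i in ids
                )
        return out
    if instrument == HOOS:
        return {
            "pain": score_hoos_subscale(responses, "pain"),
            "activity": score_hoos_subscale(responses, "adl"),
        }
    if instrument == HOOS12:
        inst = load_instrument(HOOS)
        _validate_codes(responses, inst)
        h12 = load_hoos12_map()
        return {
            "pain": _score_item_group(responses, h12["pain"]),
            "activity": _score_item_group(responses, h12["function"]),
        }
    raise UnknownItemError(f"unknown instrument {instrument!r}")


def best_responses(instrument: str) -> dict[str, int]:
    """The best-option response vector (maximum score) for an instrument."""
    inst = load_instrument(HOOS if instrument == HOOS12 else instrument)
    out: dict[str, int] = {}
    for it in inst.items:
        best_code = max(it.options, key=lambda cp: cp[1])[0]
        if inst.name == HOOS:
            best_code = 0
        out[it.item_id] = best_code
    return out


def worst_responses(instrument: str) -> dict[str, int]:
    """The worst-option response vector (minimum score) for an instrument."""
    inst = load_instrument(HOOS if instrument == HOOS12 else instrument)
    out: dict[str, int] = {}
    for it in inst.items:
        worst_code = min(it.options, key=lambda cp: cp[1])[0]
        if inst.name == HOOS:
            worst_code = 4
        out[it.item_id] = worst_code
    return out


def score_visit(
    responses: Mapping[str, int | None],
    instrument: str,
    *,
    patient_id: str = "",
    timepoint: str = "",
) -> ScoreRecord:
    """Dispatch to the scoring engine for ``instrument``."""
    if instrument == MHHS:
        return score_mhhs(responses, patient_id=patient_id, timepoint=timepoint)
    if instrument == HOOS:
        return score_hoos_total(responses, patient_id=patient_id, timepoint=timepoint)
    if instrument == HOOS12:
        return extract_hoos12(responses, patient_id=patient_id, timepoint=timepoint)
    raise UnknownItemError(f"unknown instrument {instrument!r}")
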