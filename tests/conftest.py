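"""Shared fixtures: small matched-pair builders and session-scoped cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from promwalk import HOOS, MHHS, MatchedPairSet
from promwalk import io as pio
from promwalk.cohort import CohortConfig, exact_fig1_config, generate_cohort
from promwalk.instruments import load_instrument


def make_pairs(
    x,
    y,
    range_x=(0.0, 100.0),
    range_y=(0.0, 100.0),
    instrument_x="X",
    instrument_y="Y",
    timepoints=None,
) -> MatchedPairSet:
    """Build a MatchedPairSet from two score sequences."""
    x = list(x)
    y = list(y)
    tps = list(timepoints) if timepoints is not None else ["preop"] * len(x)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(len(x))],
            "timepoint": tps,
            "score_x": x,
            "score_y": y,
        }
    )
    return MatchedPairSet(df, instrument_x, instrument_y, range_x, range_y)


def graded_responses(instrument: str, level: int) -> dict[str, int]:
    """A uniform-severity response vector: option index `level` on every item
    (clamped to each item's option count)."""
    inst = load_instrument(HOOS if instrument == "HOOS-12" else instrument)
    out = {}
    for it in inst.items:
        idx = min(level, len(it.options) - 1)
        out[it.item_id] = it.options[idx][0]
    return out


def responses_frame(visits) -> pd.DataFrame:
    """Long-format responses table from (pid, tp, instrument, {item: code}) tuples."""
    rows = []
    for pid, tp, inst, resp in visits:
        for item_id, code in resp.items():
            rows.append((pid, tp, inst, item_id, code))
    return pd.DataFrame(
        rows, columns=["patient_id", "timepoint", "instrument", "item_id", "code"]
    )


@pytest.fixture(scope="session")
def cohort_121():
    """Exact-counts cohort emulating the derivation study: 121 matched visits."""
    return generate_cohort(exact_fig1_config(seed=20))


@pytest.fixture(scope="session")
def scores_121(cohort_121):
    return pio.score_responses(cohort_121.responses)


@pytest.fixture(scope="session")
def cohort_500():
    """Large default-parameter cohort used for calibration checks."""
    return generate_cohort(CohortConfig(n_patients=500, seed=0))


@pytest.fixture(scope="session")
def scores_500(cohort_500):
    return pio.score_responses(cohort_500.responses)


@pytest.fixture(scope="session")
def pairs_121(scores_121):
    return pio.matched_pairs_from_scores(scores_121, MHHS, HOOS)
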