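"""Synthetic THA-recovery cohort with matched mHHS and HOOS responses.

The generator emulates the statistical structure the crosswalk analysis
assumes, without any patient data:

* each patient carries a latent hip-health trait on an abstract 0-1 scale
  (0 = worst).  Pre-operative traits are low; per-time-point recovery
  shifts raise them post-operatively, with extra visit-level noise at
  3 months where recovery is most heterogeneous (so 3-month scores are
  more variable than pre-operative ones);
* at a completed visit the patient answers *both* instruments.  Each
  instrument sees the shared visit trait plus an instrument-specific
  discordance deviation (patients answer similarly worded questions
  differently across forms);
* each item converts the instrument-level trait into a response code
  through equal-width severity thresholds, jittered per item by Gaussian
  noise, so higher traits never produce worse codes at fixed noise.

Defaults emulate the derivation cohort: 49 patients with per-time-point
completion probabilities matching 35/32/30/24 matched visits in
expectation (an exact-counts mode reproduces them exactly), and noise
levels calibrated so that matched totals correlate at Spearman ≈ 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .instruments import HOOS, MHHS, TIMEPOINTS, load_instrument

#: matched visits per time point in the emulated derivation cohort
FIG1_COUNTS: dict[str, int] = {"preop": 35, "3m": 32, "6m": 30, "12m": 24}


def _default_completion() -> dict[str, float]:
    return {tp: FIG1_COUNTS[tp] / 49.0 for tp in TIMEPOINTS}


def _default_shift() -> dict[str, float]:
    return {"preop": 0.0, "3m": 0.22, "6m": 0.30, "12m": 0.34}


def _default_visit_sd() -> dict[str, float]:
    return {"preop": 0.03, "3m": 0.12, "6m": 0.06, "12m": 0.05}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    All latent quantities live on the abstract 0-1 health-trait scale.
    """

    n_patients: int = 49
    seed: int = 0
    completion_probs: Mapping[str, float] = field(default_factory=_default_completion)
    exact_counts: Mapping[str, int] | None = None
    preop_mean: float = 0.35
    preop_sd: float = 0.17
    recovery_shift: Mapping[str, float] = field(default_factory=_default_shift)
    visit_sd: Mapping[str, float] = field(default_factory=_default_visit_sd)
    discordance_sd: float = 0.055
    item_noise_sd: float = 0.10
    target_spearman: float = 0.9

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be at least 2")
        for tp, p in self.completion_probs.items():
            if tp not in TIMEPOINTS:
                raise ConfigError(f"unknown timepoint {tp!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"completion probability for {tp} not in [0, 1]")
        for name, v in (
            ("preop_sd", self.preop_sd),
            ("discordance_sd", self.discordance_sd),
            ("item_noise_sd", self.item_noise_sd),
        ):
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
        if any(sd < 0 for sd in self.visit_sd.values()):
            raise ConfigError("visit_sd values must be non-negative")
        if not -1.0 <= self.target_spearman <= 1.0:
            raise ConfigError("target_spearman must be in [-1, 1]")
        if self.target_spearman >= 1.0 and (
            self.discordance_sd > 0 or self.item_noise_sd > 0
        ):
            raise ConfigError(
                "target_spearman = 1 is impossible with positive discordance "
                "or item noise; set both sds to 0 for perfectly concordant scores"
            )
        if self.exact_counts is not None:
            for tp, c in self.exact_counts.items():
                if tp not in TIMEPOINTS:
                    raise ConfigError(f"unknown timepoint {tp!r} in exact_counts")
                if c > self.n_patients:
                    raise ConfigError(
                        f"exact count {c} for {tp} exceeds n_patients {self.n_patients}"
                    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated item responses plus the ground-truth latent traits.

    ``responses`` is the long-format table
    (patient_id, timepoint, instrument, item_id, code); ``latent`` records
    one row per completed visit with the shared trait and each
    instrument's discordant trait, for recovery tests only.
    """

    responses: pd.DataFrame
    latent: pd.DataFrame
    config: CohortConfig

    def matched_visits(self) -> pd.DataFrame:
        """(patient_id, timepoint) rows at which both instruments exist."""
        return self.latent[["patient_id", "timepoint"]].copy()


def _codes_from_trait(
    trait: float, items, noise: np.ndarray
) -> list[int]:
    """Map an instrument-level trait to item codes via jittered thresholds.

    ``severity = clip(1 − trait + noise_i, 0, 1)`` is cut into as many
    equal-width bands as the item has options; band k selects the k-th
    least-severe option.  Monotone: at fixed noise, a higher trait never
    yields a worse code.
    """
    codes = []
    for it, eps in zip(items, noise):
        k = len(it.options)
        sev = min(max(1.0 - trait + eps, 0.0), 1.0 - 1e-12)
        idx = int(sev * k)
        # options are ordered by code; for both instruments here, ascending
        # code means ascending severity (mHHS points descend, HOOS points = code)
        codes.append(it.options[idx][0])
    return codes


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a matched-instrument cohort under ``config``.

    Identical config (including seed) gives byte-identical output.  A visit
    is either completed on both instruments or absent entirely.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    mhhs_items = load_instrument(MHHS).items
    hoos_items = load_instrument(HOOS).items

    baseline = rng.normal(cfg.preop_mean, cfg.preop_sd, size=cfg.n_patients)
    patient_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]

    if cfg.exact_counts is not None:
        completed: dict[str, np.ndarray] = {}
        for tp in TIMEPOINTS:
            count = int(cfg.exact_counts.get(tp, 0))
            chosen = rng.choice(cfg.n_patients, size=count, replace=False)
            mask = np.zeros(cfg.n_patients, dtype=bool)
            mask[chosen] = True
            completed[tp] = mask
    else:
        completed = {
            tp: rng.random(cfg.n_patients) < cfg.completion_probs.get(tp, 0.0)
            for tp in TIMEPOINTS
        }

    resp_rows: list[tuple] = []
    latent_rows: list[tuple] = []
    for i, pid in enumerate(patient_ids):
        for tp in TIMEPOINTS:
            if not completed[tp][i]:
                continue
            trait = (
                baseline[i]
                + cfg.recovery_shift.get(tp, 0.0)
                + rng.normal(0.0, cfg.visit_sd.get(tp, 0.0))
            )
            per_inst = {}
            for inst_name, items in ((MHHS, mhhs_items), (HOOS, hoos_items)):
                inst_trait = trait + rng.normal(0.0, cfg.discordance_sd)
                inst_trait = min(max(inst_trait, 0.0), 1.0)
                noise = rng.normal(0.0, cfg.item_noise_sd, size=len(items))
                codes = _codes_from_trait(inst_trait, items, noise)
                per_inst[inst_name] = inst_trait
                for it, code in zip(items, codes):
                    resp_rows.append((pid, tp, inst_name, it.item_id, code))
            latent_rows.append(
                (pid, tp, trait, per_inst[MHHS], per_inst[HOOS])
            )

    responses = pd.DataFrame(
        resp_rows,
        columns=["patient_id", "timepoint", "instrument", "item_id", "code"],
    )
    latent = pd.DataFrame(
        latent_rows,
        columns=["patient_id", "timepoint", "trait", "trait_mhhs", "trait_hoos"],
    )
    return SyntheticCohort(responses, latent, cfg)


def exact_fig1_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default config in exact-counts mode: 121 matched visits (35/32/30/24)."""
    return replace(CohortConfig(seed=seed, exact_counts=dict(FIG1_COUNTS)), **overrides)


def to_csv(cohort: SyntheticCohort, responses_path, latent_path=None) -> None:
    """Write the cohort: responses CSV, and optionally the latent sidecar.

    The responses file round-trips losslessly through the package reader
    and never contains the ground-truth traits.
    """
    cohort.responses.to_csv(responses_path, index=False)
    if latent_path is not None:
        cohort.latent.to_csv(latent_path, index=False)
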