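"""Seeded synthetic cohorts with the statistical structure of the two
clinical datasets the analysis targets.

Neither source publishes individual-level data, so two generators stand in
(both clearly synthetic):

* :func:`make_ma_like_cohort` — a dosing/outcome cohort of 138 patients
  (86 life-threatening, 52 non-life-threatening) whose labels track a true
  steady-state-concentration threshold near 6 mg/L, with a small label-flip
  noise.  Dose rate and infusion duration are drawn log-uniformly over wide
  ranges so that concentration and AUC decorrelate (long low-rate vs short
  high-rate regimens).
* :func:`make_auc_study_like` — 321 whole-course AUCs at 1000 mg/m^2 per
  24 h (94 with non-life-threatening toxicity, 227 without), drawn from
  per-group truncated normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import CohortRecord, Toxicity
from .model import SolverSettings, simulate
from .parameters import (
    Physiology,
    SubstanceParameters,
    default_physiology,
    default_substance,
)
from .regimen import DosingRegimen

__all__ = [
    "MaCohortSpec",
    "AucStudySpec",
    "make_ma_like_cohort",
    "make_auc_study_like",
]


@dataclass(frozen=True)
class MaCohortSpec:
    """Generator settings for the dosing/outcome cohort."""

    n_life_threatening: int = 86
    n_other: int = 52
    true_css_threshold_mg_per_L: float = 6.0
    label_noise: float = 0.02
    dose_rate_range_mg_per_h: tuple[float, float] = (50.0, 2000.0)
    duration_range_h: tuple[float, float] = (0.25, 96.0)
    body_weight_kg: float = 73.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_life_threatening <= 0 or self.n_other <= 0:
            raise ValueError("class counts must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for name in ("dose_rate_range_mg_per_h", "duration_range_h"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be positive and ordered")
        if not self.true_css_threshold_mg_per_L > 0:
            raise ValueError("true_css_threshold_mg_per_L must be positive")


@dataclass(frozen=True)
class AucStudySpec:
    """Generator settings for the AUC-study dataset (all 24-h infusions)."""

    n_tox: int = 94
    n_no_tox: int = 227
    tox_auc_mean: float = 82.2
    tox_auc_sd: float = 21.8
    no_tox_auc_mean: float = 58.3
    no_tox_auc_sd: float = 21.0
    auc_range: tuple[float, float] = (9.5, 126.3)
    infusion_time_h: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tox <= 0 or self.n_no_tox <= 0:
            raise ValueError("group counts must be positive")
        if self.tox_auc_sd <= 0 or self.no_tox_auc_sd <= 0:
            raise ValueError("group SDs must be positive")
        lo, hi = self.auc_range
        if not lo < hi:
            raise ValueError("auc_range must be ordered")
        if not self.infusion_time_h > 0:
            raise ValueError("infusion_time_h must be positive")
        for mean in (self.tox_auc_mean, self.no_tox_auc_mean):
            if not lo < mean < hi:
                raise ValueError(
                    "infeasible truncation: a group mean must lie strictly "
                    "inside the AUC range"
                )


def _exposure_metric(
    dose_mg: float,
    duration_h: float,
    physiology: Physiology,
    substance: SubstanceParameters,
) -> float:
    """Css-like labeling metric: plateau for infusions >= 5 h, else peak.

    Computed through the identical pathway the cohort analysis uses, so a
    generated label always agrees with the exposure value later fitted
    against (no spurious boundary disagreements from numerics).
    """
    from . import exposure
    from .model import COHORT_SOLVER_SETTINGS, simulate_to_washout

    regimen = (
        DosingRegimen.bolus(dose_mg)
        if duration_h == 0
        else DosingRegimen.infusion(dose_mg, duration_h)
    )
    profile = simulate_to_washout(
        regimen, physiology, substance, COHORT_SOLVER_SETTINGS
    )
    return exposure.summarize(profile).css_mg_per_L


def make_ma_like_cohort(
    spec: MaCohortSpec | None = None,
    substance: SubstanceParameters | None = None,
) -> list[CohortRecord]:
    """Rejection-sample a cohort with the requested class composition.

    (dose rate, duration) pairs are drawn log-uniformly, each candidate is
    simulated through the PBPK model, labeled life-threatening iff its
    modeled peak/plateau concentration exceeds the true threshold, the
    label is flipped with probability ``label_noise``, and candidates are
    kept while their class quota is open.  Deterministic for a fixed seed.
    """
    spec = spec if spec is not None else MaCohortSpec()
    substance = substance if substance is not None else default_substance()
    physiology = default_physiology(spec.body_weight_kg)
    rng = np.random.default_rng(spec.seed)

    need = {
        True: spec.n_life_threatening,
        False: spec.n_other,
    }
    budget = 60 * (spec.n_life_threatening + spec.n_other)
    log_rate = tuple(math.log(v) for v in spec.dose_rate_range_mg_per_h)
    log_dur = tuple(math.log(v) for v in spec.duration_range_h)

    records: list[CohortRecord] = []
    draws = 0
    while need[True] > 0 or need[False] > 0:
        draws += 1
        if draws > budget:
            raise RuntimeError(
                f"could not reach the requested class composition within "
                f"{budget} draws; widen dose_rate_range_mg_per_h or "
                f"duration_range_h, or move the threshold"
            )
        rate = math.exp(rng.uniform(*log_rate))
        duration = math.exp(rng.uniform(*log_dur))
        dose = rate * duration
        metric = _exposure_metric(dose, duration, physiology, substance)
        label = metric > spec.true_css_threshold_mg_per_L
        if rng.random() < spec.label_noise:
            label = not label
        if need[label] > 0:
            need[label] -= 1
            records.append(
                CohortRecord(
                    id=f"ma-{len(records) + 1:03d}",
                    dose_mg=dose,
                    duration_h=duration,
                    body_weight_kg=spec.body_weight_kg,
                    toxicity=(
                        Toxicity.LIFE_THREATENING
                        if label
                        else Toxicity.NON_LIFE_THREATENING
                    ),
                )
            )
    return records


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean."""
    from scipy.optimize import brentq

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return brentq(gap, target_mean - 5 * sd, target_mean + 5 * sd, xtol=1e-10)


def make_auc_study_like(spec: AucStudySpec | None = None) -> pd.DataFrame:
    """Truncated-normal AUC draws per toxicity group.

    Returns a DataFrame with columns ``auc_mg_h_per_L``,
    ``infusion_time_h`` and ``toxicity`` (codes ``nlt`` / ``none``); the
    steady-state concentration follows downstream as AUC / infusion time.
    Deterministic for a fixed seed.
    """
    spec = spec if spec is not None else AucStudySpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.auc_range

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        # Moment-match the location so the *truncated* mean equals the
        # group mean (the printed group statistics describe the truncated
        # sample, not an unobservable parent normal).
        loc = _truncnorm_loc(mean, sd, lo, hi)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)

    tox = draw(spec.n_tox, spec.tox_auc_mean, spec.tox_auc_sd)
    no_tox = draw(spec.n_no_tox, spec.no_tox_auc_mean, spec.no_tox_auc_sd)
    return pd.DataFrame(
        {
            "auc_mg_h_per_L": np.concatenate([tox, no_tox]),
            "infusion_time_h": spec.infusion_time_h,
            "toxicity": [Toxicity.NON_LIFE_THREATENING.value] * spec.n_tox
            + [Toxicity.NONE.value] * spec.n_no_tox,
        }
    )
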