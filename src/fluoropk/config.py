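"""YAML/JSON configuration: full override of model parameters and run specs.

Every tabulated constant can be replaced from a config file, e.g.::

    body_weight_kg: 49
    substance:
      km_mg_per_L: 11.1        # alternative literature value
    tissues:
      skin: {partition: 5.0}
    blood:
      total_volume_L: 5.0
    bsa_m2: 1.75
    solver: {rtol: 1.0e-8, atol: 1.0e-10}
    ma_cohort: {n_life_threatening: 86, n_other: 52, seed: 1}
    auc_study: {n_tox: 94, n_no_tox: 227, seed: 1}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import SolverSettings
from .parameters import (
    ARTERIAL_BLOOD_FRACTION,
    DEFAULT_BSA_M2,
    REFERENCE_BODY_WEIGHT_KG,
    REFERENCE_TOTAL_BLOOD_L,
    Physiology,
    SubstanceParameters,
    default_physiology,
    default_substance,
)
from .synthetic import AucStudySpec, MaCohortSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a model/pipeline run."""

    physiology: Physiology
    substance: SubstanceParameters
    solver: SolverSettings
    bsa_m2: float = DEFAULT_BSA_M2
    vmax_scale: float = 1.0
    bin_width_mg_per_L: float = 1.0
    ma_cohort: MaCohortSpec = field(default_factory=MaCohortSpec)
    auc_study: AucStudySpec = field(default_factory=AucStudySpec)
    raw: dict = field(default_factory=dict)

    def scaled_substance(self) -> SubstanceParameters:
        if self.vmax_scale == 1.0:
            return self.substance
        return self.substance.scaled(self.vmax_scale)


def _replace_from(obj, mapping: dict, context: str):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in mapping.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return replace(obj, **coerced)


def load_config(
    path: str | Path | None = None,
    body_weight_kg: float | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig`, applying overrides from a YAML/JSON file.

    ``body_weight_kg`` given in code takes precedence over the file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")

    bw = body_weight_kg
    if bw is None:
        bw = float(raw.get("body_weight_kg", REFERENCE_BODY_WEIGHT_KG))
    physiology = default_physiology(bw)

    for name, changes in (raw.get("tissues") or {}).items():
        physiology = physiology.with_tissue(name, **changes)

    blood = raw.get("blood") or {}
    if blood:
        total = float(
            blood.get(
                "total_volume_L",
                REFERENCE_TOTAL_BLOOD_L * bw / REFERENCE_BODY_WEIGHT_KG,
            )
        )
        art_frac = float(blood.get("arterial_fraction", ARTERIAL_BLOOD_FRACTION))
        physiology = replace(
            physiology,
            arterial_blood_volume_L=art_frac * total,
            venous_blood_volume_L=(1 - art_frac) * total,
        )

    substance = _replace_from(
        default_substance(), raw.get("substance") or {}, "substance"
    )
    solver = _replace_from(SolverSettings(), raw.get("solver") or {}, "solver")
    ma = _replace_from(MaCohortSpec(), raw.get("ma_cohort") or {}, "ma_cohort")
    auc = _replace_from(AucStudySpec(), raw.get("auc_study") or {}, "auc_study")

    return RunConfig(
        physiology=physiology,
        substance=substance,
        solver=solver,
        bsa_m2=float(raw.get("bsa_m2", DEFAULT_BSA_M2)),
        vmax_scale=float(raw.get("vmax_scale", 1.0)),
        bin_width_mg_per_L=float(raw.get("bin_width_mg_per_L", 1.0)),
        ma_cohort=ma,
        auc_study=auc,
        raw=raw,
    )


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the raw configuration (for output stamping)."""
    payload = json.dumps(config.raw, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
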