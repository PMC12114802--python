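"""Physiological and substance parameter sets for the 5-FU disposition model.

The model body is a perfusion-limited compartment network: nine tissues
(fat, liver, brain, kidney, muscle, skin, vessel-rich tissue, skeleton,
red marrow) connected through arterial and venous blood pools.  Lungs and
heart close the circulation as a zero-volume pass-through.  Only the liver
metabolizes drug, with Michaelis-Menten kinetics.

Reference physiology follows ICRP-style adult values at 73 kg body weight.
Only the muscle and skin volumes scale with body weight (muscle
0.40 * bw, skin 0.0371 * bw); all other volumes and all blood flows stay
at their reference values.  Blood volume (5.3 L at reference, split 1/3
arterial and 2/3 venous) scales linearly with body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "TissueParameters",
    "Physiology",
    "SubstanceParameters",
    "default_physiology",
    "default_substance",
    "dubois_bsa_m2",
    "REFERENCE_BODY_WEIGHT_KG",
    "DEFAULT_BSA_M2",
]

REFERENCE_BODY_WEIGHT_KG = 73.0
REFERENCE_CARDIAC_OUTPUT_L_PER_H = 401.7
REFERENCE_TOTAL_BLOOD_L = 5.3
ARTERIAL_BLOOD_FRACTION = 1.0 / 3.0

#: Default body surface area used to resolve mg/m^2 doses when no
#: patient-specific value is supplied.
DEFAULT_BSA_M2 = 1.8

# name, blood flow (L/h), volume (L; None = body-weight coefficient below),
# tissue:blood partition coefficient, metabolizing
_REFERENCE_TISSUES = (
    ("fat", 19.5, 18.2, 0.20, False),
    ("liver", 99.5, 1.8, 0.92, True),
    ("brain", 46.8, 1.45, 1.35, False),
    ("kidney", 74.1, 0.31, 0.98, False),
    ("muscle", 65.8, None, 2.19, False),
    ("skin", 20.0, None, 10.04, False),
    ("vessel_rich", 44.8, 2.6, 0.98, False),
    ("skeleton", 7.8, 6.9, 0.63, False),
    ("red_marrow", 11.7, 1.2, 0.92, False),
)

_WEIGHT_COEFFICIENTS = {"muscle": 0.40, "skin": 0.0371}


@dataclass(frozen=True)
class TissueParameters:
    """One perfusion-limited compartment.

    Parameters
    ----------
    name : str
        Tissue label.
    volume_L : float
        Tissue volume V_T in litres.
    flow_L_per_h : float
        Blood flow Q_T through the tissue in L/h.
    partition : float
        Tissue:blood partition coefficient P_T (dimensionless).  The venous
        outflow of a perfusion-limited tissue carries C_T / P_T.
    metabolizing : bool
        Whether the tissue eliminates drug (liver only in the default model).
    """

    name: str
    volume_L: float
    flow_L_per_h: float
    partition: float
    metabolizing: bool = False

    def __post_init__(self) -> None:
        for attr in ("volume_L", "flow_L_per_h", "partition"):
            if not getattr(self, attr) > 0:
                raise ValueError(
                    f"tissue {self.name!r}: {attr} must be positive, "
                    f"got {getattr(self, attr)!r}"
                )


@dataclass(frozen=True)
class Physiology:
    """Whole-body parameter set: tissue network plus blood pools."""

    body_weight_kg: float
    cardiac_output_L_per_h: float
    tissues: tuple[TissueParameters, ...]
    arterial_blood_volume_L: float
    venous_blood_volume_L: float

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise ValueError("body_weight_kg must be positive")
        for attr in (
            "cardiac_output_L_per_h",
            "arterial_blood_volume_L",
            "venous_blood_volume_L",
        ):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be positive")
        if not self.tissues:
            raise ValueError("at least one tissue compartment is required")
        n_met = sum(t.metabolizing for t in self.tissues)
        if n_met != 1:
            raise ValueError(
                f"exactly one metabolizing tissue is required, got {n_met}"
            )
        # The printed per-tissue flows need not sum exactly to cardiac output
        # (pass-through lung/heart absorb the bookkeeping); allow 5% headroom.
        if self.total_tissue_flow_L_per_h > 1.05 * self.cardiac_output_L_per_h:
            raise ValueError(
                "sum of tissue flows exceeds cardiac output by more than 5%"
            )
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("tissue names must be unique")

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tissues)

    @property
    def total_tissue_flow_L_per_h(self) -> float:
        """Effective cardiac output: the flow actually routed through tissues.

        Used for the venous -> arterial transfer so that compartment-level
        mass balance is exact even when the listed flows do not add up to
        the nominal cardiac output.
        """
        return float(sum(t.flow_L_per_h for t in self.tissues))

    @property
    def liver_index(self) -> int:
        return next(i for i, t in enumerate(self.tissues) if t.metabolizing)

    @property
    def liver(self) -> TissueParameters:
        return self.tissues[self.liver_index]

    def volumes(self) -> np.ndarray:
        return np.array([t.volume_L for t in self.tissues])

    def flows(self) -> np.ndarray:
        return np.array([t.flow_L_per_h for t in self.tissues])

    def partitions(self) -> np.ndarray:
        return np.array([t.partition for t in self.tissues])

    def tissue(self, name: str) -> TissueParameters:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def with_tissue(self, name: str, **changes) -> "Physiology":
        """Return a copy with one tissue's parameters replaced."""
        tissues = tuple(
            replace(t, **changes) if t.name == name else t for t in self.tissues
        )
        return replace(self, tissues=tissues)


@dataclass(frozen=True)
class SubstanceParameters:
    """Drug-specific constants.

    ``vmax_mg_per_h`` and ``km_mg_per_L`` parameterize saturable hepatic
    elimination; the remaining fields are physicochemical metadata carried
    along for provenance (they do not enter the kinetics — the partition
    coefficients are supplied per tissue).
    """

    vmax_mg_per_h: float
    km_mg_per_L: float
    log_kow: float = float("nan")
    pka: float = float("nan")
    fraction_bound: float = float("nan")

    def __post_init__(self) -> None:
        if not self.vmax_mg_per_h > 0:
            raise ValueError("vmax_mg_per_h must be positive")
        if not self.km_mg_per_L > 0:
            raise ValueError("km_mg_per_L must be positive")

    def scaled(self, vmax_factor: float) -> "SubstanceParameters":
        """Multiplicatively scale Vmax (inter-subject clearance bands)."""
        if not vmax_factor > 0:
            raise ValueError("vmax_factor must be positive")
        return replace(self, vmax_mg_per_h=self.vmax_mg_per_h * vmax_factor)


def default_physiology(body_weight_kg: float = REFERENCE_BODY_WEIGHT_KG) -> Physiology:
    """Reference adult physiology, optionally rescaled to a body weight.

    Muscle and skin volumes are proportional to body weight; the other
    organ volumes and all flows keep their 73-kg reference values.  Blood
    volume scales linearly with body weight.
    """
    if not body_weight_kg > 0:
        raise ValueError("body_weight_kg must be positive")
    tissues = []
    for name, flow, volume, partition, metabolizing in _REFERENCE_TISSUES:
        if volume is None:
            volume = _WEIGHT_COEFFICIENTS[name] * body_weight_kg
        tissues.append(
            TissueParameters(
                name=name,
                volume_L=volume,
                flow_L_per_h=flow,
                partition=partition,
                metabolizing=metabolizing,
            )
        )
    blood = REFERENCE_TOTAL_BLOOD_L * body_weight_kg / REFERENCE_BODY_WEIGHT_KG
    return Physiology(
        body_weight_kg=body_weight_kg,
        cardiac_output_L_per_h=REFERENCE_CARDIAC_OUTPUT_L_PER_H,
        tissues=tuple(tissues),
        arterial_blood_volume_L=ARTERIAL_BLOOD_FRACTION * blood,
        venous_blood_volume_L=(1.0 - ARTERIAL_BLOOD_FRACTION) * blood,
    )


def default_substance() -> SubstanceParameters:
    """5-fluorouracil constants.

    Vmax 1221.7 mg/h and Km 11.7 mg/L (population-PK means for hepatic
    DPD-mediated elimination).  An alternative Km of 11.1 mg/L circulates in
    the same literature and can be supplied via configuration.  Protein
    binding is reported as 8-12%; the midpoint is stored as metadata.
    """
    return SubstanceParameters(
        vmax_mg_per_h=1221.7,
        km_mg_per_L=11.7,
        log_kow=-0.89,
        pka=8.02,
        fraction_bound=0.10,
    )


def dubois_bsa_m2(height_cm: float, weight_kg: float) -> float:
    """DuBois & DuBois body surface area (m^2)."""
    if not (height_cm > 0 and weight_kg > 0):
        raise ValueError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425
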