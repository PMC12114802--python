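"""Cohort-level exposure/toxicity analysis.

Three stages: simulate every patient's dosing record to get per-patient
exposure (Css, AUC); tabulate toxicity fractions in fixed-width
concentration bins; and fit a depth-1 classification tree (decision
stump) asking whether Css or AUC better separates toxic outcomes, and at
what threshold.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import exposure
from .model import (
    COHORT_SOLVER_SETTINGS,
    SolverSettings,
    simulate_to_washout,
)
from .parameters import Physiology, SubstanceParameters, default_physiology, default_substance
from .regimen import DosingRegimen

__all__ = [
    "Toxicity",
    "CohortRecord",
    "ExposureToxicityRow",
    "CohortExposure",
    "simulate_cohort",
    "BinnedToxicityTable",
    "binned_fraction",
    "StumpModel",
    "StumpPrediction",
    "fit_stump",
    "predict_stump",
    "read_cohort_csv",
    "write_cohort_csv",
]


class Toxicity(enum.Enum):
    """Toxicity strata, with their CSV codes."""

    NONE = "none"
    NON_LIFE_THREATENING = "nlt"
    LIFE_THREATENING = "lt"

    @classmethod
    def parse(cls, value) -> "Toxicity":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown toxicity code {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def _is_life_threatening(t: Toxicity) -> bool:
    return t is Toxicity.LIFE_THREATENING


def _is_any_toxicity(t: Toxicity) -> bool:
    return t is not Toxicity.NONE


@dataclass(frozen=True)
class CohortRecord:
    """One patient's dosing and outcome. ``duration_h == 0`` means bolus."""

    id: str
    dose_mg: float
    duration_h: float
    body_weight_kg: float = 73.0
    toxicity: Toxicity = Toxicity.NONE

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ValueError(f"record {self.id!r}: dose_mg must be positive")
        if self.duration_h < 0:
            raise ValueError(f"record {self.id!r}: duration_h must be non-negative")
        if not self.body_weight_kg > 0:
            raise ValueError(f"record {self.id!r}: body_weight_kg must be positive")
        object.__setattr__(self, "toxicity", Toxicity.parse(self.toxicity))

    def regimen(self) -> DosingRegimen:
        if self.duration_h == 0:
            return DosingRegimen.bolus(self.dose_mg)
        return DosingRegimen.infusion(self.dose_mg, self.duration_h)


@dataclass(frozen=True)
class ExposureToxicityRow:
    """Derived exposure for one record.

    For administrations shorter than 5 h no steady state exists;
    ``css_mg_per_L`` then holds the peak concentration and ``no_plateau``
    is set.
    """

    id: str
    css_mg_per_L: float
    auc_mg_h_per_L: float
    toxicity: Toxicity
    no_plateau: bool = False

    def __post_init__(self) -> None:
        if self.css_mg_per_L < 0 or self.auc_mg_h_per_L < 0:
            raise ValueError(f"row {self.id!r}: exposure metrics must be >= 0")


@dataclass
class CohortExposure:
    """Result container: exposure rows plus any per-record failures."""

    rows: list[ExposureToxicityRow]
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[ExposureToxicityRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, i):
        return self.rows[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.rows],
                "css_mg_per_L": [r.css_mg_per_L for r in self.rows],
                "auc_mg_h_per_L": [r.auc_mg_h_per_L for r in self.rows],
                "no_plateau": [r.no_plateau for r in self.rows],
                "toxicity": [r.toxicity.value for r in self.rows],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortExposure":
        rows = [
            ExposureToxicityRow(
                id=str(rec.id),
                css_mg_per_L=float(rec.css_mg_per_L),
                auc_mg_h_per_L=float(rec.auc_mg_h_per_L),
                toxicity=Toxicity.parse(rec.toxicity),
                no_plateau=bool(getattr(rec, "no_plateau", False)),
            )
            for rec in df.itertuples()
        ]
        return cls(rows=rows)


def simulate_cohort(
    records: Sequence[CohortRecord],
    physiology_factory: Callable[[float], Physiology] = default_physiology,
    substance: SubstanceParameters | None = None,
    settings: SolverSettings | None = None,
) -> CohortExposure:
    """Simulate every record and derive its exposure row.

    Per-record failures are collected (and warned about) rather than
    aborting the run.  ``physiology_factory`` maps a body weight to a
    :class:`Physiology`; pass a lambda ignoring its argument to pin one.
    """
    substance = substance if substance is not None else default_substance()
    settings = settings if settings is not None else COHORT_SOLVER_SETTINGS
    out = CohortExposure(rows=[])
    for rec in records:
        try:
            profile = simulate_to_washout(
                rec.regimen(),
                physiology_factory(rec.body_weight_kg),
                substance,
                settings,
            )
            summary = exposure.summarize(profile)
            out.rows.append(
                ExposureToxicityRow(
                    id=rec.id,
                    css_mg_per_L=summary.css_mg_per_L,
                    auc_mg_h_per_L=summary.auc_mg_h_per_L,
                    toxicity=rec.toxicity,
                    no_plateau=summary.no_plateau,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            warnings.warn(f"record {rec.id!r} failed: {exc}", stacklevel=2)
            out.failures.append((rec.id, str(exc)))
    return out


# ---------------------------------------------------------------------------
# concentration binning


@dataclass(frozen=True)
class BinnedToxicityTable:
    """Toxicity fraction per right-open concentration bin [k*w, (k+1)*w)."""

    bin_edges_mg_per_L: np.ndarray
    n_total: np.ndarray
    n_with_effect: np.ndarray

    @property
    def fraction_with_effect(self) -> np.ndarray:
        """Per-bin fraction; NaN where the bin is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_total > 0, self.n_with_effect / self.n_total, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_mg_per_L": self.bin_edges_mg_per_L[:-1],
                "bin_hi_mg_per_L": self.bin_edges_mg_per_L[1:],
                "n_total": self.n_total,
                "n_with_effect": self.n_with_effect,
                "fraction_with_effect": self.fraction_with_effect,
            }
        )


def binned_fraction(
    rows: Iterable[ExposureToxicityRow],
    bin_width_mg_per_L: float = 1.0,
    positive: Callable[[Toxicity], bool] = _is_any_toxicity,
) -> BinnedToxicityTable:
    """Fraction of toxic outcomes per concentration bin.

    Bins are right-open, of fixed width, anchored at 0 mg/L, and cover the
    full observed Css range.  Empty bins are reported with ``n_total`` 0
    and an undefined (NaN) fraction.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("at least one row is required")
    if not bin_width_mg_per_L > 0:
        raise ValueError("bin width must be positive")
    css = np.array([r.css_mg_per_L for r in rows])
    pos = np.array([positive(r.toxicity) for r in rows], dtype=bool)
    n_bins = max(1, int(math.floor(css.max() / bin_width_mg_per_L)) + 1)
    edges = bin_width_mg_per_L * np.arange(n_bins + 1)
    idx = np.minimum(
        (css / bin_width_mg_per_L).astype(int), n_bins - 1
    )  # right-open bins; top edge value cannot occur since max < last edge
    n_total = np.bincount(idx, minlength=n_bins)
    n_pos = np.bincount(idx[pos], minlength=n_bins)
    return BinnedToxicityTable(
        bin_edges_mg_per_L=edges, n_total=n_total, n_with_effect=n_pos
    )


# ---------------------------------------------------------------------------
# decision stump

_STUMP_FEATURES = ("css", "auc")
_GAIN_EPS = 1e-12


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


@dataclass(frozen=True)
class StumpModel:
    """A depth-1 classification tree over the (css, auc) feature pair.

    ``feature is None`` marks the degenerate single-leaf model fitted on
    single-class data (or data with no usable split); it predicts the
    majority class everywhere.
    """

    feature: str | None
    threshold: float
    counts_below: tuple[int, int]  # (negatives, positives) in the left leaf
    counts_above: tuple[int, int]
    impurity_gain: float
    n_samples: int
    n_positive: int

    @property
    def is_degenerate(self) -> bool:
        return self.feature is None

    @property
    def prob_below(self) -> float:
        n = sum(self.counts_below)
        return self.counts_below[1] / n if n else float("nan")

    @property
    def prob_above(self) -> float:
        n = sum(self.counts_above)
        return self.counts_above[1] / n if n else float("nan")

    @property
    def leaf_probabilities(self) -> tuple[float, float]:
        return (self.prob_below, self.prob_above)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": None if self.is_degenerate else self.threshold,
            "counts_below": list(self.counts_below),
            "counts_above": list(self.counts_above),
            "prob_below": self.prob_below,
            "prob_above": self.prob_above,
            "impurity_gain": self.impurity_gain,
            "n_samples": self.n_samples,
            "n_positive": self.n_positive,
        }


@dataclass(frozen=True)
class StumpPrediction:
    positive: bool
    probability: float


def fit_stump(
    rows: Iterable[ExposureToxicityRow],
    positive: Callable[[Toxicity], bool] = _is_life_threatening,
) -> StumpModel:
    """Exhaustive single-split search over both features.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values of each feature (CART convention); the split maximizing the
    Gini impurity decrease wins.  Ties go to the earlier feature
    (css before auc) and, within a feature, to the smaller threshold.
    Single-class input yields the degenerate majority model.
    """
    rows = list(rows)
    if len(rows) < 1:
        raise ValueError("at least one row is required")
    y = np.array([positive(r.toxicity) for r in rows], dtype=bool)
    n = len(y)
    n_pos = int(y.sum())
    features = {
        "css": np.array([r.css_mg_per_L for r in rows]),
        "auc": np.array([r.auc_mg_h_per_L for r in rows]),
    }

    best: tuple[float, str, float] | None = None  # (gain, feature, threshold)
    parent = _gini(n_pos, n)
    if 0 < n_pos < n:
        for name in _STUMP_FEATURES:
            x = features[name]
            order = np.argsort(x, kind="stable")
            xs, ys = x[order], y[order]
            distinct, starts = np.unique(xs, return_index=True)
            # positives among rows with value <= distinct[k]
            cum_pos = np.cumsum(ys)
            group_end = np.append(starts[1:], n) - 1
            pos_le = cum_pos[group_end]
            n_le = np.append(starts[1:], n)
            for k in range(len(distinct) - 1):
                thr = 0.5 * (distinct[k] + distinct[k + 1])
                n_lo = int(n_le[k])
                pos_lo = int(pos_le[k])
                gain = parent - (
                    n_lo * _gini(pos_lo, n_lo)
                    + (n - n_lo) * _gini(n_pos - pos_lo, n - n_lo)
                ) / n
                if best is None or gain > best[0] + _GAIN_EPS:
                    best = (gain, name, thr)

    if best is None:
        return StumpModel(
            feature=None,
            threshold=float("nan"),
            counts_below=(n - n_pos, n_pos),
            counts_above=(0, 0),
            impurity_gain=0.0,
            n_samples=n,
            n_positive=n_pos,
        )

    gain, name, thr = best
    x = features[name]
    below = x <= thr
    pos_below = int(y[below].sum())
    n_below = int(below.sum())
    return StumpModel(
        feature=name,
        threshold=thr,
        counts_below=(n_below - pos_below, pos_below),
        counts_above=((n - n_below) - (n_pos - pos_below), n_pos - pos_below),
        impurity_gain=gain,
        n_samples=n,
        n_positive=n_pos,
    )


def predict_stump(
    model: StumpModel,
    row: ExposureToxicityRow | None = None,
    *,
    css: float | None = None,
    auc: float | None = None,
) -> StumpPrediction:
    """Threshold test on the model's feature; leaf probability attached."""
    if model.is_degenerate:
        p = model.n_positive / model.n_samples
        return StumpPrediction(positive=p >= 0.5, probability=p)
    if row is not None:
        value = row.css_mg_per_L if model.feature == "css" else row.auc_mg_h_per_L
    else:
        value = css if model.feature == "css" else auc
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing value for feature {model.feature!r}")
    p = model.prob_below if value <= model.threshold else model.prob_above
    return StumpPrediction(positive=p >= 0.5, probability=p)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read a cohort table: id, dose_mg, duration_h[, body_weight_kg], toxicity."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "dose_mg", "duration_h", "toxicity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns {sorted(missing)}")
    records = []
    for rec in df.itertuples():
        records.append(
            CohortRecord(
                id=str(rec.id),
                dose_mg=float(rec.dose_mg),
                duration_h=float(rec.duration_h),
                body_weight_kg=float(getattr(rec, "body_weight_kg", 73.0)),
                toxicity=Toxicity.parse(rec.toxicity),
            )
        )
    return records


def write_cohort_csv(records: Sequence[CohortRecord], path, header_lines=None) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "dose_mg": [r.dose_mg for r in records],
            "duration_h": [r.duration_h for r in records],
            "body_weight_kg": [r.body_weight_kg for r in records],
            "toxicity": [r.toxicity.value for r in records],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
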