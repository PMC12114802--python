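"""Exposure metrics: AUC, Cmax, steady-state and early ("dynamic") concentrations.

Two routes to the steady-state concentration coexist, mirroring clinical
practice: ``css_from_auc`` (the model-independent identity
``C_ss = AUC / infusion time``, applied by TDM studies to whole-course
AUCs) and ``css_observed`` (the simulated plateau of a constant-rate
infusion profile).  ``fraction_of_steady_state`` and
``predict_css_from_cdyn`` implement early-sampling TDM: one hour into a
24-h infusion roughly half the plateau is reached, so an early measured
concentration ("C_dyn") forecasts the eventual plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConcentrationTimeProfile

__all__ = [
    "ExposureSummary",
    "PlateauEstimate",
    "auc",
    "cmax",
    "css_from_auc",
    "css_observed",
    "fraction_of_steady_state",
    "predict_css_from_cdyn",
    "summarize",
]

#: Full-profile AUC horizon: integrate until the venous concentration has
#: decayed below this fraction of its peak.
AUC_CUTOFF_FRACTION = 1e-3

#: Plateau window default: the final tenth of the infusion.
PLATEAU_WINDOW_FRACTION = 0.1

#: Relative plateau slope above which the estimate is flagged non-plateau.
PLATEAU_MAX_REL_SLOPE_PER_H = 0.01


@dataclass(frozen=True)
class ExposureSummary:
    """Per-profile PK metrics (all concentrations mg/L, AUC mg*h/L)."""

    cmax_mg_per_L: float
    auc_mg_h_per_L: float
    css_mg_per_L: float
    cdyn_mg_per_L: float
    t_sample_h: float
    no_plateau: bool = False


@dataclass(frozen=True)
class PlateauEstimate:
    """Mean concentration over a late-infusion window plus a quality flag."""

    value: float
    is_plateau: bool
    rel_slope_per_h: float

    def __float__(self) -> float:
        return self.value


def _full_profile_end(t: np.ndarray, c: np.ndarray) -> float:
    """Truncation time for the full-profile AUC."""
    ipeak = int(np.argmax(c))
    peak = c[ipeak]
    if peak <= 0:
        return float(t[-1])
    below = np.nonzero(c[ipeak:] < AUC_CUTOFF_FRACTION * peak)[0]
    if below.size == 0:
        return float(t[-1])
    return float(t[ipeak + below[0]])


def auc(
    profile: ConcentrationTimeProfile,
    t0: float | None = None,
    t1: float | None = None,
) -> float:
    """Trapezoidal area under the venous concentration curve (mg*h/L).

    With no interval given, integrates from the grid start until the
    concentration has fallen below 0.1% of the peak (or the grid end).
    Explicit ``t0``/``t1`` must lie within the grid; off-grid endpoints are
    linearly interpolated, so adjacent intervals split at a shared grid
    point add exactly.
    """
    t = profile.time_h
    c = profile.c_venous
    if len(t) == 0:
        raise ValueError("empty profile")
    if t0 is None:
        t0 = float(t[0])
    if t1 is None:
        t1 = _full_profile_end(t, c)
    if not (t[0] - 1e-12 <= t0 < t1 <= t[-1] + 1e-12):
        raise ValueError(
            f"integration interval [{t0}, {t1}] outside profile grid "
            f"[{t[0]}, {t[-1]}]"
        )
    inside = (t > t0) & (t < t1)
    ts = np.concatenate(([t0], t[inside], [t1]))
    cs = np.concatenate(
        ([np.interp(t0, t, c)], c[inside], [np.interp(t1, t, c)])
    )
    return float(np.trapezoid(cs, ts))


def cmax(profile: ConcentrationTimeProfile) -> float:
    """Peak venous concentration over the grid (mg/L)."""
    if len(profile.time_h) == 0:
        raise ValueError("empty profile")
    return float(np.max(profile.c_venous))


def css_from_auc(auc_mg_h_per_L: float, infusion_time_h: float) -> float:
    """Model-independent steady-state concentration: ``AUC / infusion time``."""
    if not infusion_time_h > 0:
        raise ValueError("infusion_time_h must be positive")
    if auc_mg_h_per_L < 0:
        raise ValueError("auc must be non-negative")
    return auc_mg_h_per_L / infusion_time_h


def _single_infusion(profile: ConcentrationTimeProfile):
    reg = profile.regimen
    if not reg.is_single_infusion:
        raise ValueError(
            "plateau metrics require a single constant-rate infusion regimen"
        )
    return reg.realized_events()[0]


def css_observed(
    profile: ConcentrationTimeProfile, window_h: float | None = None
) -> PlateauEstimate:
    """Plateau concentration of a constant-rate infusion profile.

    Mean venous concentration over a window ending at the infusion end
    (default: the final 10% of the infusion).  The window must lie within
    the final third of the infusion.  The estimate is flagged non-plateau
    when the relative slope exceeds 1%/h.
    """
    ev = _single_infusion(profile)
    duration = ev.duration_h
    if window_h is None:
        window_h = PLATEAU_WINDOW_FRACTION * duration
    if not 0 < window_h <= duration / 3 + 1e-12:
        raise ValueError(
            f"window_h={window_h} must lie within the final third of the "
            f"{duration} h infusion"
        )
    lo = ev.start_h + duration - window_h
    hi = ev.start_h + duration
    t = profile.time_h
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("profile grid too coarse for the plateau window")
    tw = t[mask]
    cw = profile.c_venous[mask]
    mean = float(np.mean(cw))
    slope = float(np.polyfit(tw, cw, 1)[0])
    rel_slope = slope / mean if mean > 0 else np.inf
    return PlateauEstimate(
        value=mean,
        is_plateau=abs(rel_slope) <= PLATEAU_MAX_REL_SLOPE_PER_H,
        rel_slope_per_h=rel_slope,
    )


def fraction_of_steady_state(profile: ConcentrationTimeProfile, t: float) -> float:
    """Fraction of the infusion plateau attained at time ``t``."""
    plateau = css_observed(profile).value
    if plateau <= 0:
        raise ValueError("profile has no positive plateau")
    return profile.venous_at(t) / plateau


def predict_css_from_cdyn(cdyn_mg_per_L: float, fraction: float = 0.5) -> float:
    """Forecast the plateau from an early sample: ``C_ss = C_dyn / fraction``.

    The default fraction 0.5 encodes that about half of the steady state is
    reached one hour into a standard 24-h infusion.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if cdyn_mg_per_L < 0:
        raise ValueError("cdyn must be non-negative")
    return cdyn_mg_per_L / fraction


#: Shortest infusion for which a plateau (steady state) is considered reached.
PLATEAU_MIN_INFUSION_H = 5.0


def summarize(
    profile: ConcentrationTimeProfile, cdyn_time_h: float = 1.0
) -> ExposureSummary:
    """Full metric set for one profile.

    ``css`` is the infusion plateau for single infusions of at least
    5 h; shorter administrations have no steady state, so the peak is
    reported in its place with ``no_plateau`` set.  ``cdyn`` is sampled
    ``cdyn_time_h`` after the first administration starts.
    """
    peak = cmax(profile)
    area = auc(profile)
    reg = profile.regimen
    no_plateau = True
    css = peak
    if reg.is_single_infusion:
        ev = reg.realized_events()[0]
        if ev.duration_h >= PLATEAU_MIN_INFUSION_H:
            css = css_observed(profile).value
            no_plateau = False
    start = min((e.start_h for e in reg.events), default=0.0)
    t_sample = start + cdyn_time_h
    cdyn = profile.venous_at(t_sample) if t_sample <= profile.time_h[-1] else 0.0
    return ExposureSummary(
        cmax_mg_per_L=peak,
        auc_mg_h_per_L=area,
        css_mg_per_L=css,
        cdyn_mg_per_L=cdyn,
        t_sample_h=t_sample,
        no_plateau=no_plateau,
    )
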