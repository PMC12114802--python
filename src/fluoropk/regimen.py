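"""Intravenous dosing schedules: timed bolus and constant-rate infusion events."""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import DEFAULT_BSA_M2

__all__ = ["DoseEvent", "DosingRegimen", "BOLUS_REALIZATION_H"]

#: An iv bolus is realized as a constant-rate infusion of this duration
#: (1 minute), which avoids discontinuous initial conditions while keeping
#: bolus kinetics on the 0.1-h scale.
BOLUS_REALIZATION_H = 1.0 / 60.0


@dataclass(frozen=True)
class DoseEvent:
    """A single iv administration. ``duration_h == 0`` means bolus."""

    dose_mg: float
    start_h: float = 0.0
    duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be non-negative")
        if self.start_h < 0:
            raise ValueError("start_h must be non-negative")
        if self.duration_h < 0:
            raise ValueError("duration_h must be non-negative")

    @property
    def is_bolus(self) -> bool:
        return self.duration_h == 0.0

    def realized(self) -> "DoseEvent":
        """The event as integrated: boluses become 1-minute infusions."""
        if self.is_bolus:
            return DoseEvent(self.dose_mg, self.start_h, BOLUS_REALIZATION_H)
        return self

    @property
    def rate_mg_per_h(self) -> float:
        ev = self.realized()
        return ev.dose_mg / ev.duration_h

    @property
    def end_h(self) -> float:
        ev = self.realized()
        return ev.start_h + ev.duration_h


@dataclass(frozen=True)
class DosingRegimen:
    """An ordered, non-overlapping sequence of iv dose events."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, DoseEvent) else DoseEvent(*e) for e in self.events
        )
        object.__setattr__(self, "events", events)
        realized = sorted((e.realized() for e in events), key=lambda e: e.start_h)
        for prev, nxt in zip(realized, realized[1:]):
            if nxt.start_h < prev.start_h + prev.duration_h - 1e-12:
                raise ValueError(
                    f"overlapping dose events at t={nxt.start_h} h "
                    f"(previous event runs to {prev.start_h + prev.duration_h} h)"
                )

    # -- constructors -------------------------------------------------
    @classmethod
    def infusion(
        cls, dose_mg: float, duration_h: float, start_h: float = 0.0
    ) -> "DosingRegimen":
        return cls((DoseEvent(dose_mg, start_h, duration_h),))

    @classmethod
    def bolus(cls, dose_mg: float, start_h: float = 0.0) -> "DosingRegimen":
        return cls((DoseEvent(dose_mg, start_h, 0.0),))

    @classmethod
    def from_dose_per_m2(
        cls,
        dose_per_m2: float,
        duration_h: float,
        bsa_m2: float = DEFAULT_BSA_M2,
        start_h: float = 0.0,
    ) -> "DosingRegimen":
        """Resolve a mg/m^2 dose to mg via a body surface area."""
        if not bsa_m2 > 0:
            raise ValueError("bsa_m2 must be positive")
        return cls((DoseEvent(dose_per_m2 * bsa_m2, start_h, duration_h),))

    # -- queries ------------------------------------------------------
    @property
    def total_dose_mg(self) -> float:
        return float(sum(e.dose_mg for e in self.events))

    def realized_events(self) -> tuple[DoseEvent, ...]:
        return tuple(
            sorted((e.realized() for e in self.events), key=lambda e: e.start_h)
        )

    @property
    def end_h(self) -> float:
        """End of the last realized administration (0 for an empty regimen)."""
        realized = self.realized_events()
        return max((e.end_h for e in realized), default=0.0)

    @property
    def is_single_infusion(self) -> bool:
        """True for a regimen consisting of one constant-rate event."""
        return len(self.events) == 1

    def rate_at(self, t: float) -> float:
        """Instantaneous iv input rate (mg/h) at time ``t``."""
        rate = 0.0
        for e in self.realized_events():
            if e.start_h <= t < e.start_h + e.duration_h:
                rate += e.rate_mg_per_h
        return rate

    def breakpoints(self) -> list[float]:
        """Times at which the input rate may jump (event starts and ends)."""
        pts: set[float] = set()
        for e in self.realized_events():
            pts.add(e.start_h)
            pts.add(e.start_h + e.duration_h)
        return sorted(pts)

    def to_dict(self) -> dict:
        return {
            "events": [
                {"dose_mg": e.dose_mg, "start_h": e.start_h, "duration_h": e.duration_h}
                for e in self.events
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DosingRegimen":
        return cls(
            tuple(
                DoseEvent(ev["dose_mg"], ev["start_h"], ev["duration_h"])
                for ev in d["events"]
            )
        )
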