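"""Measurement schedule for the irradiance-step experiment.

Plants grow under low light (LL) and are switched to high light (HL); the
quantum yield of photosystem II electron transport (Phi_PSII) is imaged a
few times per day before and after the switch.  The default schedule is
two LL days followed by four HL days with three measurement slots per day
at 9.00, 11.30 and 14.30 h (photoperiod starting at 8.00 h), i.e. 18 time
points in total.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TimePoint", "MeasurementSchedule", "default_schedule"]


@dataclass(frozen=True)
class TimePoint:
    """One scheduled measurement.

    ``day`` is 1-based across the whole experiment, ``slot`` is 1-based
    within the day, ``clock_hour`` is the time of day in hours and
    ``phase`` is ``"LL"`` or ``"HL"``.
    """

    day: int
    slot: int
    clock_hour: float
    phase: str


@dataclass(frozen=True)
class MeasurementSchedule:
    """Ordered measurement time points, LL days strictly before HL days."""

    time_points: tuple[TimePoint, ...]
    photoperiod_start: float = 8.0

    def __post_init__(self) -> None:
        phases = [tp.phase for tp in self.time_points]
        if any(p not in ("LL", "HL") for p in phases):
            raise ValueError("phases must be 'LL' or 'HL'")
        if "LL" in phases[phases.index("HL"):] if "HL" in phases else False:
            raise ValueError("LL time points must precede all HL time points")

    def __len__(self) -> int:
        return len(self.time_points)

    def __iter__(self):
        return iter(self.time_points)

    @property
    def n_ll(self) -> int:
        return sum(tp.phase == "LL" for tp in self.time_points)

    @property
    def n_hl(self) -> int:
        return sum(tp.phase == "HL" for tp in self.time_points)

    @property
    def ll_indices(self) -> list[int]:
        return [i for i, tp in enumerate(self.time_points) if tp.phase == "LL"]

    @property
    def hl_indices(self) -> list[int]:
        return [i for i, tp in enumerate(self.time_points) if tp.phase == "HL"]

    @property
    def first_hl_day(self) -> int:
        hl = [tp.day for tp in self.time_points if tp.phase == "HL"]
        if not hl:
            raise ValueError("schedule has no HL time points")
        return min(hl)

    def hl_day_index(self, tp: TimePoint) -> int:
        """1-based day index within the HL phase (1 = first HL day)."""
        if tp.phase != "HL":
            raise ValueError("time point is not in the HL phase")
        return tp.day - self.first_hl_day + 1

    def hours_since_hl_onset(self, tp: TimePoint) -> float:
        """Elapsed time in hours from the start of the photoperiod on the
        first HL day (the moment the irradiance is stepped up)."""
        if tp.phase != "HL":
            raise ValueError("time point is not in the HL phase")
        return (tp.day - self.first_hl_day) * 24.0 + (
            tp.clock_hour - self.photoperiod_start
        )

    def labels(self) -> list[str]:
        return [f"d{tp.day}s{tp.slot}" for tp in self.time_points]


def default_schedule(
    n_ll_days: int = 2,
    n_hl_days: int = 4,
    slot_hours: tuple[float, ...] = (9.0, 11.5, 14.5),
    photoperiod_start: float = 8.0,
) -> MeasurementSchedule:
    """Build the standard 2 LL + 4 HL day schedule (3 slots/day, 18 points)."""
    tps = []
    day = 0
    for _ in range(n_ll_days):
        day += 1
        for slot, h in enumerate(slot_hours, start=1):
            tps.append(TimePoint(day=day, slot=slot, clock_hour=h, phase="LL"))
    for _ in range(n_hl_days):
        day += 1
        for slot, h in enumerate(slot_hours, start=1):
            tps.append(TimePoint(day=day, slot=slot, clock_hour=h, phase="HL"))
    return MeasurementSchedule(tuple(tps), photoperiod_start=photoperiod_start)
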