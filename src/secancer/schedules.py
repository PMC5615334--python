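"""Treatment calendars: fraction times, cycle starts, concurrent overlays.

Day 0 is a Monday by convention, so the weekday pattern of a course is
reproducible; ``start_day`` offsets shift the weekday phase.  Calendar
construction is a pure function of the course description.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model_core import ChemoCourse, ConcurrentCourse, RadiationCourse

__all__ = [
    "CalendarEvent",
    "EventCalendar",
    "build_rt_calendar",
    "build_chemo_calendar",
    "build_concurrent_calendar",
]


@dataclass(frozen=True)
class CalendarEvent:
    t: float
    kind: str  # "rt_fraction" | "chemo_cycle_start"
    magnitude: float  # Gy or mg/m^2


@dataclass
class EventCalendar:
    """Time-sorted treatment events."""

    events: list[CalendarEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.t, e.kind))
        rt_days = [e.t for e in self.events if e.kind == "rt_fraction"]
        if len(set(rt_days)) != len(rt_days):
            raise ValueError("two radiotherapy fractions on the same day")

    def __len__(self) -> int:
        return len(self.events)

    def times(self, kind: str | None = None) -> list[float]:
        return [e.t for e in self.events if kind is None or e.kind == kind]

    def merge(self, other: "EventCalendar") -> "EventCalendar":
        return EventCalendar(self.events + other.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.t, e.kind, e.magnitude) for e in self.events],
            columns=["t", "kind", "magnitude"],
        )


def _is_weekday(day: int) -> bool:
    return day % 7 < 5  # day 0 = Monday


def build_rt_calendar(course: RadiationCourse) -> EventCalendar:
    """Fraction times for a fractionated course.

    With 5 fractions/week, fractions fall on consecutive weekdays and
    weekends are skipped (20 fractions span 26 calendar days).  With 7
    fractions/week, fractions are daily.
    """
    times: list[int] = []
    day = int(course.start_day)
    while len(times) < course.K_R:
        if course.fractions_per_week == 7 or _is_weekday(day):
            times.append(day)
        day += 1
    return EventCalendar([CalendarEvent(float(t), "rt_fraction", course.d_R) for t in times])


def build_chemo_calendar(course: ChemoCourse) -> EventCalendar:
    """Cycle-start times: ``start_day + cycle_length * i``."""
    return EventCalendar(
        [
            CalendarEvent(course.start_day + course.cycle_length * i, "chemo_cycle_start", course.d_C)
            for i in range(course.K_C)
        ]
    )


def build_concurrent_calendar(course: ConcurrentCourse) -> EventCalendar:
    """Merged calendar with radiotherapy starting at chemo cycle 1.

    The radiation sub-course is re-anchored to the first chemotherapy
    cycle start.  Interaction-active windows are the days carrying an
    ``rt_fraction`` event while a cycle is ongoing.
    """
    chemo_cal = build_chemo_calendar(course.chemo)
    rc = course.radiation
    if course.chemo.K_C > 0:
        rc = RadiationCourse(
            K_R=rc.K_R,
            d_R=rc.d_R,
            fractions_per_week=rc.fractions_per_week,
            start_day=int(course.chemo.start_day),
            tau=rc.tau,
        )
    rt_cal = build_rt_calendar(rc)
    if rt_cal.events and chemo_cal.events:
        chemo_end = max(chemo_cal.times()) + course.chemo.cycle_length
        if rt_cal.events[-1].t >= chemo_end:
            warnings.warn(
                "radiotherapy course extends beyond the last chemotherapy cycle",
                stacklevel=2,
            )
    return rt_cal.merge(chemo_cal)
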