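"""Day-grid medication supply simulation under three carryover policies.

The engine answers, for each day of a patient's observation period, whether
enough medication was in hand to take the directed dose.  Supply is tracked
in dose units; each day is *available* iff the level at the start of the day
covers a full day's requirement, in which case that requirement is consumed.
New dispensings arrive at the start of their day and are banked until needed.
What happens to leftovers when a new dispensing arrives is the carryover
policy:

- DISCARD: leftovers are lost; the level resets to the newly dispensed units.
- CAP: the level after a dispensing is at most double the units dispensed.
- RETAIN: all leftovers are kept (full banking).

The regimen attached to the most recent dispensing governs consumption from
its date forward, regardless of which medication the remaining stock came
from — regimen changes take effect immediately, medication changes do not
bin stock.  Partial leftovers smaller than one day's requirement persist
(they may become usable if a later regimen lowers the daily requirement).

Although semantics are defined per day, the implementation is event-driven:
between dispensings the requirement is constant, so the run of available
days and the residual level have closed forms.  A deliberately naive
day-at-a-time reference implementation in the test-suite cross-checks this
engine exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .dose_parser import DoseRegimen
from .records_io import ObservationPeriod, PrescriptionRecord

_EPS = 1e-9  # guards floor() against float noise in level/requirement ratios


class CarryoverPolicy(str, Enum):
    DISCARD = "D"
    CAP = "C"
    RETAIN = "R"


@dataclass(frozen=True)
class SupplyEvent:
    """One (condensed) dispensing: units added and the regimen effective
    from this date."""

    date: dt.date
    units_added: float
    regimen: DoseRegimen

    def __post_init__(self) -> None:
        if self.units_added <= 0:
            raise ValueError("units_added must be positive")


@dataclass(frozen=True)
class _Segment:
    """Constant-requirement stretch between consecutive events.

    Days [start, end) (ordinals); ``level`` at segment start (after the
    event, if any); ``requirement`` units/day (0 if no regimen yet);
    ``n_available`` leading days of the segment that are available.
    """

    start: int
    end: int
    level: float
    requirement: float
    n_available: int

    def level_at_day_start(self, day: int) -> float:
        """Supply level at the start of ``day`` (before that day's
        consumption, after any event on the segment's first day)."""
        k = min(day - self.start, self.n_available)
        return self.level - k * self.requirement


@dataclass
class SupplyTimeline:
    """Per-day availability over an observation period for one policy.

    Availability is stored as a sorted list of closed day-ordinal intervals
    clipped to the period; dense per-day vectors are materialised on demand.
    """

    period: ObservationPeriod
    policy: CarryoverPolicy
    segments: list[_Segment] = field(default_factory=list)
    available_intervals: list[tuple[int, int]] = field(default_factory=list)
    event_days: frozenset[int] = frozenset()

    @property
    def n_days(self) -> int:
        return self.period.duration_days

    def availability_vector(self) -> np.ndarray:
        """Dense boolean vector, one entry per day of the period."""
        start = self.period.start_date.toordinal()
        out = np.zeros(self.n_days, dtype=bool)
        for lo, hi in self.available_intervals:
            out[lo - start : hi - start + 1] = True
        return out

    def level_vector(self) -> np.ndarray:
        """Supply level at the start of each day of the period."""
        start = self.period.start_date.toordinal()
        end = start + self.n_days  # exclusive
        out = np.zeros(self.n_days)
        for seg in self.segments:
            lo, hi = max(seg.start, start), min(seg.end, end)
            for day in range(lo, hi):
                out[day - start] = seg.level_at_day_start(day)
        return out

    def level_at_day_start(self, day: dt.date, *, before_events: bool = False) -> float:
        """Supply level at the start of a day.

        With ``before_events=True``, the level just before any dispensing on
        that day is applied — i.e. the carryover from strictly earlier
        activity, which is the stock "available at the start" of a window
        opening that day.
        """
        ordinal = day.toordinal()
        for i, seg in enumerate(self.segments):
            if seg.start <= ordinal < seg.end:
                if before_events and ordinal in self.event_days and ordinal == seg.start:
                    if i == 0:
                        return 0.0
                    return self.segments[i - 1].level_at_day_start(ordinal)
                return seg.level_at_day_start(ordinal)
        if self.segments and ordinal >= self.segments[-1].end:
            return self.segments[-1].level_at_day_start(ordinal)
        return 0.0

    def to_frame(self):
        """Per-day export (date, supply level, available flag) for debugging
        and plotting."""
        import pandas as pd

        start = self.period.start_date
        return pd.DataFrame(
            {
                "date": [start + dt.timedelta(days=i) for i in range(self.n_days)],
                "supply_level": self.level_vector(),
                "available": self.availability_vector(),
            }
        )


def condense_same_day(records: Sequence[PrescriptionRecord],
                      regimens: Sequence[DoseRegimen]) -> list[SupplyEvent]:
    """Merge same-day dispensings of one patient into single events.

    Multiple prescriptions collected on the same day are condensed into one
    event by summing the supply; the regimen of the condensed event is taken
    from the last record of that day (the regimen most recently issued).
    """
    if len(records) != len(regimens):
        raise ValueError("records and regimens must be parallel sequences")
    pairs = sorted(zip(records, regimens), key=lambda p: p[0].dispensing_date)
    events: list[SupplyEvent] = []
    for record, regimen in pairs:
        if events and events[-1].date == record.dispensing_date:
            prev = events[-1]
            events[-1] = SupplyEvent(
                date=prev.date,
                units_added=prev.units_added + record.dispensed_quantity,
                regimen=regimen,
            )
        else:
            events.append(
                SupplyEvent(record.dispensing_date, record.dispensed_quantity, regimen)
            )
    return events


def _merge_events(events: Iterable[SupplyEvent]) -> list[SupplyEvent]:
    merged: list[SupplyEvent] = []
    for ev in sorted(events, key=lambda e: e.date):
        if merged and merged[-1].date == ev.date:
            prev = merged[-1]
            merged[-1] = SupplyEvent(prev.date, prev.units_added + ev.units_added, ev.regimen)
        else:
            merged.append(ev)
    return merged


def _apply_policy(level: float, units: float, policy: CarryoverPolicy) -> float:
    if policy is CarryoverPolicy.DISCARD:
        return units
    if policy is CarryoverPolicy.CAP:
        return min(level + units, 2.0 * units)
    return level + units


def simulate_supply(
    events: Sequence[SupplyEvent],
    period: ObservationPeriod,
    policy: CarryoverPolicy,
    prior_events: Sequence[SupplyEvent] | None = None,
) -> SupplyTimeline:
    """Simulate the supply level and per-day availability over a period.

    ``prior_events`` (dispensings before the period) seed the level and
    regimen at period start; without them the level starts at zero.  The
    simulation runs from the earliest event through the period end; the
    availability intervals are clipped to the period.
    """
    all_events = _merge_events(list(prior_events or []) + list(events))
    start_ord = period.start_date.toordinal()
    end_ord = period.end_date.toordinal()
    for ev in all_events:
        if ev.date.toordinal() > end_ord:
            raise ValueError(f"event on {ev.date} falls after the simulated period end")

    sim_start = start_ord
    if all_events:
        sim_start = min(start_ord, all_events[0].date.toordinal())

    segments: list[_Segment] = []
    level = 0.0
    requirement = 0.0
    t = sim_start

    def emit(boundary: int) -> None:
        nonlocal level, t
        if boundary <= t:
            return
        if requirement > 0:
            n_avail = min(int(math.floor(level / requirement + _EPS)), boundary - t)
        else:
            n_avail = 0
        segments.append(_Segment(t, boundary, level, requirement, n_avail))
        level -= n_avail * requirement
        t = boundary

    for ev in all_events:
        emit(ev.date.toordinal())
        level = _apply_policy(level, ev.units_added, policy)
        requirement = ev.regimen.daily_units
    emit(end_ord + 1)

    intervals: list[tuple[int, int]] = []
    for seg in segments:
        if seg.n_available > 0:
            lo = max(seg.start, start_ord)
            hi = min(seg.start + seg.n_available - 1, end_ord)
            if lo <= hi:
                if intervals and intervals[-1][1] == lo - 1:
                    intervals[-1] = (intervals[-1][0], hi)
                else:
                    intervals.append((lo, hi))
    return SupplyTimeline(
        period, policy, segments, intervals,
        frozenset(ev.date.toordinal() for ev in all_events),
    )


def available_days(
    timeline: SupplyTimeline, window: tuple[dt.date, dt.date] | None = None
) -> int:
    """Count days with medication available in a closed date window."""
    if window is None:
        lo, hi = timeline.period.start_date.toordinal(), timeline.period.end_date.toordinal()
    else:
        lo, hi = window[0].toordinal(), window[1].toordinal()
        if lo < timeline.period.start_date.toordinal() or hi > timeline.period.end_date.toordinal():
            raise ValueError("window extends outside the simulated period")
    return sum(
        max(0, min(hi, b) - max(lo, a) + 1) for a, b in timeline.available_intervals
    )


def supply_exhaustion_date(
    timeline: SupplyTimeline,
    window_start: dt.date | None = None,
    events: Sequence[SupplyEvent] | None = None,
    *,
    discard_resets: bool = False,
) -> dt.date:
    """First day on which the stock held at the window start no longer
    covers a full day's requirement.

    The starting stock is the timeline's carryover level just before the
    window opens; it is drawn down by the prevailing daily requirement
    (updated immediately by any in-window regimen change) while new
    in-window acquisitions are banked and do not replenish it.  With
    ``discard_resets=True`` and a DISCARD timeline, an in-window dispensing
    that precedes the analytic exhaustion wipes the starting stock on its
    day instead.

    Zero starting stock returns the window start itself.  A return value
    after the period end means the initial stock outlasted the whole period.
    """
    start = window_start or timeline.period.start_date
    start_ord = start.toordinal()
    end_ord = timeline.period.end_date.toordinal()
    stock = timeline.level_at_day_start(start, before_events=True)
    if stock <= _EPS:
        return start

    # requirement schedule over [start, end]: prevailing regimen at start,
    # then each in-window event's regimen from its date
    changes: list[tuple[int, float]] = []
    requirement = 0.0
    for seg in timeline.segments:
        if seg.start <= start_ord:
            requirement = seg.requirement
    for ev in sorted(events or [], key=lambda e: e.date):
        o = ev.date.toordinal()
        if start_ord <= o <= end_ord:
            changes.append((o, ev.regimen.daily_units))
    if not changes and requirement <= 0:
        # stock but no regimen ever: nothing is consumed
        return dt.date.fromordinal(end_ord + 1)

    t = start_ord
    first_event = changes[0][0] if changes else None
    for boundary, new_req in changes + [(end_ord + 1, 0.0)]:
        if requirement > 0:
            k = int(math.floor(stock / requirement + _EPS))
            if t + k < boundary:
                return dt.date.fromordinal(t + k)
            stock -= (boundary - t) * requirement
        t = boundary
        if discard_resets and timeline.policy is CarryoverPolicy.DISCARD \
                and first_event is not None and boundary == first_event:
            return dt.date.fromordinal(boundary)
        requirement = new_req
    return dt.date.fromordinal(end_ord + 1)
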