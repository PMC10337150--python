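"""The eight Continuous, Multiple-interval Measures of medication
Availability (CMA1-CMA8).

CMA1-CMA4 are *acquisition* measures: supply days obtained in a window
divided by the window duration, ignoring the timing of fills within it
(CMA3/CMA4 are CMA1/CMA2 clamped at 1).  CMA5-CMA8 are *availability*
measures: the fraction of window days on which enough medication was in
hand, taken from a simulated supply timeline, so they detect gaps but not
oversupply.  The measures differ in where their analysis window starts and
ends within the observation period:

=======  =============================  ==========================
measure  window start                   window end
=======  =============================  ==========================
CMA1     day of first fill              day before final fill
CMA2     day of first fill              end of observation period
CMA3     day of first fill              day before final fill
CMA4     day of first fill              end of observation period
CMA5     day of first fill              day before final fill
CMA6     day of first fill              end of observation period
CMA7     start of observation period    end of observation period
CMA8     day initial stock exhausted    end of observation period
=======  =============================  ==========================

Windows are closed intervals of whole days; "day before final fill" makes
the window of the CMA1/3/5 family empty for a single-fill window, which is
why those measures are non-calculable without at least two fills (no refill
interval with a known end).  Non-calculable is a first-class value, never
silently zero: conflating the two would corrupt adherence distributions, as
single-fill windows are common in routine dispensing data.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .dose_parser import expected_supply_duration
from .records_io import ObservationPeriod
from .supply_engine import CarryoverPolicy, SupplyEvent, SupplyTimeline, available_days


class Measure(str, Enum):
    CMA1 = "CMA1"
    CMA2 = "CMA2"
    CMA3 = "CMA3"
    CMA4 = "CMA4"
    CMA5 = "CMA5"
    CMA6 = "CMA6"
    CMA7 = "CMA7"
    CMA8 = "CMA8"

    @property
    def is_acquisition(self) -> bool:
        return self in _ACQUISITION

    @property
    def is_availability(self) -> bool:
        return not self.is_acquisition

    @property
    def needs_two_fills(self) -> bool:
        """CMA1/3/5 need at least one refill interval with a known end."""
        return self in (Measure.CMA1, Measure.CMA3, Measure.CMA5)

    @property
    def needs_prior_history(self) -> bool:
        return self in (Measure.CMA7, Measure.CMA8)


_ACQUISITION = (Measure.CMA1, Measure.CMA2, Measure.CMA3, Measure.CMA4)

#: non-calculable sentinel
NON_CALCULABLE = float("nan")


@dataclass(frozen=True)
class AnalysisWindow:
    """Closed day interval a measure is computed over."""

    start_date: dt.date
    end_date: dt.date

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass(frozen=True)
class CmaEstimate:
    """One (patient, interval, measure, policy) adherence value.

    ``value`` is NaN when non-calculable; ``policy`` is empty for the
    acquisition measures (CMA1-4), to which carryover handling does not
    apply.
    """

    patient_id: str
    interval_label: str
    measure: Measure
    policy: CarryoverPolicy | None
    value: float
    n_prescriptions: int

    @property
    def calculable(self) -> bool:
        return not math.isnan(self.value)


def window_for_measure(
    measure: Measure,
    event_dates: Sequence[dt.date],
    period: ObservationPeriod,
    exhaustion_date: dt.date | None = None,
) -> AnalysisWindow | None:
    """Analysis window for a measure, or ``None`` when the window is empty.

    ``event_dates`` are the (condensed, sorted) fill dates inside the
    observation period; ``exhaustion_date`` is required for CMA8.
    """
    if measure is Measure.CMA7:
        return AnalysisWindow(period.start_date, period.end_date)
    if measure is Measure.CMA8:
        if exhaustion_date is None:
            raise ValueError("CMA8 requires an exhaustion date")
        if exhaustion_date > period.end_date:
            return None
        start = max(exhaustion_date, period.start_date)
        return AnalysisWindow(start, period.end_date)
    if not event_dates:
        return None
    first, last = event_dates[0], event_dates[-1]
    if measure.needs_two_fills:
        end = last - dt.timedelta(days=1)
        if end < first:
            return None  # single fill: no interval with a known end
        return AnalysisWindow(first, end)
    return AnalysisWindow(first, period.end_date)


def supply_days_obtained(
    events: Sequence[SupplyEvent], window: AnalysisWindow
) -> float:
    """Total expected supply duration of the fills dispensed in the window.

    A fill contributes iff its dispensing date lies in the closed window, so
    the final fill is excluded from the CMA1/3/5 numerators by construction
    (their window ends the day before it).
    """
    return sum(
        expected_supply_duration(ev.units_added, ev.regimen)
        for ev in events
        if window.contains(ev.date)
    )


def cma_acquisition(
    measure: Measure,
    events: Sequence[SupplyEvent],
    window: AnalysisWindow | None,
) -> float:
    """CMA1/CMA2 (supply days obtained / window duration) and their clamped
    variants CMA3 = min(CMA1, 1), CMA4 = min(CMA2, 1)."""
    if measure not in _ACQUISITION:
        raise ValueError(f"{measure} is not an acquisition measure")
    if window is None or window.duration_days <= 0:
        return NON_CALCULABLE
    ratio = supply_days_obtained(events, window) / window.duration_days
    if measure in (Measure.CMA3, Measure.CMA4):
        return min(ratio, 1.0)
    return ratio


def cma_availability(
    measure: Measure,
    timeline: SupplyTimeline,
    window: AnalysisWindow | None,
) -> float:
    """CMA5-CMA8: days with medication available in the window / window
    duration.  Guaranteed in [0, 1] whenever calculable."""
    if measure.is_acquisition:
        raise ValueError(f"{measure} is not an availability measure")
    if window is None or window.duration_days <= 0:
        return NON_CALCULABLE
    n = available_days(timeline, (window.start_date, window.end_date))
    return n / window.duration_days
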