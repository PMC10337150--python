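"""Cohort-level orchestration: windows, calculability rules, estimate table.

For every patient the observation period is cut into analysis intervals at
three granularities — the full follow-up, calendar years and calendar
quarters — and each requested measure x carryover-policy combination is
estimated inside each interval.  Calendar (not anniversary) alignment is the
default, so year/quarter windows tile the observation period exactly, with
the first and last windows possibly partial; anniversary alignment is
available behind a flag.

Calculability rules applied here:

- CMA1/3/5 need at least two fills in the interval (otherwise their window
  is empty) — the estimate is emitted as non-calculable, never as zero.
- CMA7/CMA8 need prior dispensing history to price the stock at the window
  start, so they are not emitted for a patient's first year or first
  quarter; for the full follow-up they are computed with zero prior stock
  (no carryover into the study).
- A patient whose follow-up spans zero days (single fill on the final
  observation day) has every measure non-calculable.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cma_measures import (
    NON_CALCULABLE,
    AnalysisWindow,
    Measure,
    cma_acquisition,
    cma_availability,
    window_for_measure,
)
from .dose_parser import (
    DoseRegimen,
    ParseFailure,
    Provenance,
    RangePolicy,
    parse_dose_text,
    resolve_regimen,
)
from .records_io import ObservationPeriod, PrescriptionRecord
from .supply_engine import (
    CarryoverPolicy,
    SupplyEvent,
    condense_same_day,
    simulate_supply,
    supply_exhaustion_date,
)

logger = logging.getLogger(__name__)


class Granularity(str, Enum):
    FULL = "full"
    YEAR = "year"
    QUARTER = "quarter"


ALL_MEASURES = tuple(Measure)
ALL_POLICIES = tuple(CarryoverPolicy)
ALL_GRANULARITIES = tuple(Granularity)

#: fallback regimen when the dose text cannot be parsed and no
#: formulation-specific default is configured: two units twice a day, the
#: modal directed regimen for controller inhalers.
DEFAULT_REGIMEN_FALLBACKS: dict[str, DoseRegimen] = {
    "*": DoseRegimen(2.0, 2.0, provenance=Provenance.DEFAULT),
}


@dataclass
class EstimationConfig:
    measures: tuple[Measure, ...] = ALL_MEASURES
    policies: tuple[CarryoverPolicy, ...] = ALL_POLICIES
    granularities: tuple[Granularity, ...] = ALL_GRANULARITIES
    range_policy: RangePolicy = RangePolicy.MAX
    regimen_defaults: Mapping[str, DoseRegimen] = field(
        default_factory=lambda: dict(DEFAULT_REGIMEN_FALLBACKS)
    )
    anniversary_years: bool = False
    discard_resets_exhaustion: bool = False


@dataclass
class CohortResult:
    """Long-format estimate table plus cohort-level bookkeeping."""

    table: pd.DataFrame
    n_patients: int = 0
    n_records: int = 0
    skipped_patients: dict[str, str] = field(default_factory=dict)
    parse_failures: Counter = field(default_factory=Counter)
    n_default_regimens: int = 0


def split_intervals(
    period: ObservationPeriod,
    granularity: Granularity,
    *,
    anniversary: bool = False,
) -> list[tuple[str, AnalysisWindow]]:
    """Tile an observation period into labelled analysis windows.

    Calendar years/quarters intersected with the period; first and last
    windows may be partial.  The windows partition the period exactly.
    """
    start, end = period.start_date, period.end_date
    if granularity is Granularity.FULL:
        return [("full", AnalysisWindow(start, end))]
    if anniversary:
        return _anniversary_windows(period, granularity)
    windows: list[tuple[str, AnalysisWindow]] = []
    if granularity is Granularity.YEAR:
        for year in range(start.year, end.year + 1):
            lo = max(start, dt.date(year, 1, 1))
            hi = min(end, dt.date(year, 12, 31))
            windows.append((str(year), AnalysisWindow(lo, hi)))
    else:
        year, quarter = start.year, (start.month - 1) // 3 + 1
        while True:
            q_start = dt.date(year, 3 * quarter - 2, 1)
            q_end = (
                dt.date(year + 1, 1, 1) if quarter == 4 else dt.date(year, 3 * quarter + 1, 1)
            ) - dt.timedelta(days=1)
            lo, hi = max(start, q_start), min(end, q_end)
            windows.append((f"{year}Q{quarter}", AnalysisWindow(lo, hi)))
            if q_end >= end:
                break
            quarter += 1
            if quarter == 5:
                quarter, year = 1, year + 1
    return windows


def _anniversary_windows(
    period: ObservationPeriod, granularity: Granularity
) -> list[tuple[str, AnalysisWindow]]:
    step_months = 12 if granularity is Granularity.YEAR else 3
    prefix = "Y" if granularity is Granularity.YEAR else "Q"
    windows: list[tuple[str, AnalysisWindow]] = []
    k = 0
    lo = period.start_date
    while lo <= period.end_date:
        nxt = _add_months(period.start_date, (k + 1) * step_months)
        hi = min(period.end_date, nxt - dt.timedelta(days=1))
        windows.append((f"{prefix}{k + 1}", AnalysisWindow(lo, hi)))
        lo = nxt
        k += 1
    return windows


def _add_months(day: dt.date, months: int) -> dt.date:
    month = day.month - 1 + months
    year = day.year + month // 12
    month = month % 12 + 1
    try:
        return day.replace(year=year, month=month)
    except ValueError:  # e.g. Feb 29 / month-end overflow
        return dt.date(year, month, 1) + dt.timedelta(days=27)


_TABLE_COLUMNS = (
    "patient_id",
    "granularity",
    "interval_label",
    "window_index",
    "measure",
    "policy",
    "value",
    "n_prescriptions",
)


def estimate_cohort(
    records: Sequence[PrescriptionRecord],
    periods: Mapping[str, ObservationPeriod],
    config: EstimationConfig | None = None,
) -> CohortResult:
    """Estimate every requested (measure, policy) for every patient window.

    ``records`` may be unsorted; per-patient validation failures skip the
    patient with a logged reason rather than aborting the cohort.
    """
    config = config or EstimationConfig()
    result = CohortResult(table=pd.DataFrame(), n_records=len(records))

    by_patient: dict[str, list[PrescriptionRecord]] = defaultdict(list)
    for rec in records:
        by_patient[rec.patient_id].append(rec)

    rows: list[tuple] = []
    for pid, recs in by_patient.items():
        period = periods.get(pid)
        if period is None:
            result.skipped_patients[pid] = "no observation period"
            continue
        try:
            rows.extend(_estimate_patient(pid, recs, period, config, result))
        except Exception as exc:  # pragma: no cover - defensive per-patient skip
            result.skipped_patients[pid] = str(exc)
            logger.warning("patient %s skipped: %s", pid, exc)

    result.n_patients = len(by_patient) - len(result.skipped_patients)
    result.table = pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))
    return result


def _estimate_patient(
    pid: str,
    recs: list[PrescriptionRecord],
    period: ObservationPeriod,
    config: EstimationConfig,
    result: CohortResult,
) -> list[tuple]:
    recs = sorted(recs, key=lambda r: r.dispensing_date)

    regimens: list[DoseRegimen] = []
    kept: list[PrescriptionRecord] = []
    for rec in recs:
        parsed = parse_dose_text(rec.dose_text, config.range_policy)
        if isinstance(parsed, ParseFailure):
            result.parse_failures[parsed.reason] += 1
        regimen = resolve_regimen(rec, parsed, config.regimen_defaults)
        if regimen is None:
            result.parse_failures["non-analysable"] += 1
            continue
        if regimen.provenance is Provenance.DEFAULT:
            result.n_default_regimens += 1
        kept.append(rec)
        regimens.append(regimen)

    # events outside the observation period do not enter the analysis (no
    # carryover into the study; nothing can be dispensed after its end)
    events = [
        ev
        for ev in condense_same_day(kept, regimens)
        if period.start_date <= ev.date <= period.end_date
    ]

    zero_followup = period.duration_days <= 1

    rows: list[tuple] = []
    for gran in config.granularities:
        windows = split_intervals(period, gran, anniversary=config.anniversary_years)

        needs_period_tl = any(m.needs_prior_history for m in config.measures)
        full_tl = (
            {
                pol: simulate_supply(events, period, pol)
                for pol in config.policies
            }
            if needs_period_tl and not zero_followup
            else {}
        )

        for idx, (label, window) in enumerate(windows):
            win_events = [ev for ev in events if window.contains(ev.date)]
            n_presc = len(win_events)
            dates = [ev.date for ev in win_events]
            win_period = ObservationPeriod(pid, window.start_date, window.end_date)

            win_tl = {}
            if not zero_followup and any(
                m in (Measure.CMA5, Measure.CMA6) for m in config.measures
            ):
                win_tl = {
                    pol: simulate_supply(win_events, win_period, pol)
                    for pol in config.policies
                }

            for measure in config.measures:
                if zero_followup:
                    if measure.needs_prior_history and gran is not Granularity.FULL and idx == 0:
                        continue
                    for pol in (None,) if measure.is_acquisition else config.policies:
                        rows.append(
                            (pid, gran.value, label, idx, measure.value,
                             pol.value if pol else "", NON_CALCULABLE, n_presc)
                        )
                    continue

                if measure.is_acquisition:
                    win = window_for_measure(measure, dates, win_period)
                    value = cma_acquisition(measure, win_events, win)
                    rows.append(
                        (pid, gran.value, label, idx, measure.value, "", value, n_presc)
                    )
                elif measure in (Measure.CMA5, Measure.CMA6):
                    win = window_for_measure(measure, dates, win_period)
                    for pol in config.policies:
                        value = cma_availability(measure, win_tl[pol], win)
                        rows.append(
                            (pid, gran.value, label, idx, measure.value, pol.value,
                             value, n_presc)
                        )
                else:  # CMA7 / CMA8
                    if gran is not Granularity.FULL and idx == 0:
                        continue  # first year/quarter: no prior history
                    for pol in config.policies:
                        tl = full_tl[pol]
                        if measure is Measure.CMA7:
                            win = window_for_measure(measure, dates, win_period)
                        else:
                            exhaustion = supply_exhaustion_date(
                                tl,
                                window_start=window.start_date,
                                events=win_events,
                                discard_resets=config.discard_resets_exhaustion,
                            )
                            win = window_for_measure(
                                measure, dates, win_period, exhaustion_date=exhaustion
                            )
                        value = cma_availability(measure, tl, win)
                        rows.append(
                            (pid, gran.value, label, idx, measure.value, pol.value,
                             value, n_presc)
                        )
    return rows


def summarise_distribution(
    table: pd.DataFrame,
    measure: Measure | str,
    granularity: Granularity | str | None = None,
    policy: CarryoverPolicy | str | None = None,
) -> pd.DataFrame:
    """Median / IQR / range / n of calculable estimates, stratified by
    whether the window held a single or multiple fills."""
    measure = getattr(measure, "value", measure)
    sub = table[table["measure"] == measure]
    if granularity is not None:
        sub = sub[sub["granularity"] == getattr(granularity, "value", granularity)]
    if policy is not None:
        sub = sub[sub["policy"] == getattr(policy, "value", policy)]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        return pd.DataFrame(
            columns=["median", "q1", "q3", "min", "max", "n"],
            index=pd.Index([], name="stratum"),
        )

    def _stats(values: pd.Series) -> dict:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return {
            "median": med, "q1": q1, "q3": q3,
            "min": values.min(), "max": values.max(), "n": len(values),
        }

    strata = {"all": sub}
    strata["single"] = sub[sub["n_prescriptions"] <= 1]
    strata["multiple"] = sub[sub["n_prescriptions"] >= 2]
    out = {
        name: _stats(frame["value"]) for name, frame in strata.items() if len(frame)
    }
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.index.name = "stratum"
    return frame
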