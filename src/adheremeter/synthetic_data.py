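"""Synthetic prescription cohorts with the schema and statistical structure
of linked primary-care dispensing data.

The generator emits per-patient streams of dispensed prescriptions — with
raw free-text dose directions drawn from a library of clean and messy
variants, so the dose parser is exercised end-to-end rather than bypassed —
plus observation periods and a ground-truth table holding each patient's
latent adherence propensity and true per-window proportion of days covered.

The default spec emulates a long-running asthma-controller cohort observed
over roughly eight years: a left-skewed follow-up distribution (median about
7 years, upper quartile near the study length), about one patient in six
with only a single fill, roughly half of refills collected before the
previous supply ran out (oversupply), occasional regimen switches, and a
minority of as-needed (prn) directions.  Adherence propensity evolves
year-to-year as an AR(1) process on the logit scale, giving persistent but
drifting behaviour.

Everything is reproducible from the spec's seed: the same spec yields
byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import Granularity, split_intervals
from .records_io import ObservationPeriod, PrescriptionRecord


@dataclass(frozen=True)
class RegimenTemplate:
    """A directed regimen plus the text variants a prescriber might type."""

    dose_quantity: float
    frequency_per_day: float
    pack_units: float
    texts: tuple[str, ...]

    @property
    def daily_units(self) -> float:
        return self.dose_quantity * self.frequency_per_day

    @property
    def pack_duration_days(self) -> float:
        return self.pack_units / self.daily_units


#: controller-inhaler style regimen library: (units x per-day, pack size)
DEFAULT_REGIMEN_LIBRARY: tuple[RegimenTemplate, ...] = (
    RegimenTemplate(2, 2, 120, (
        "TWO PUFFS TWICE A DAY",
        "2 puffs bd",
        "Take two puffs twice daily",
        "2 puffs twice a day",
    )),
    RegimenTemplate(1, 2, 120, (
        "1 puff bd",
        "one puff twice a day",
        "Take 1 puff morning and evening",
    )),
    RegimenTemplate(2, 1, 60, (
        "2 puffs od",
        "two puffs once daily",
        "2 puffs every morning",
    )),
    RegimenTemplate(1, 1, 30, (
        "1 od",
        "take one tablet daily",
        "1 tablet once a day",
    )),
    RegimenTemplate(2, 2, 200, (
        "two puffs bd",
        "2 puffs twice daily",
    )),
)

_PRN_SUFFIXES = (" prn", " as required", " when needed")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; the defaults are the reference
    study conditions."""

    n_patients: int = 1000
    seed: int = 0
    study_start: dt.date = dt.date(2009, 1, 1)
    study_end: dt.date = dt.date(2017, 3, 31)
    # follow-up duration ~ max_years * Beta(a, b): median ~7y, IQR ~4.3-8.0
    followup_beta: tuple[float, float] = (0.93, 0.35)
    max_followup_years: float = 8.2
    min_followup_days: int = 90
    # latent adherence propensity on (0, 1]
    propensity_beta: tuple[float, float] = (3.5, 1.5)
    fixed_propensity: float | None = None
    propensity_rho: float = 0.7  # year-to-year AR(1) on the logit scale
    propensity_sigma: float = 0.5  # innovation s.d. on the logit scale
    # refill-interval model
    single_fill_fraction: float = 0.167
    early_refill_prob: float = 0.45  # refill before previous supply runs out
    early_refill_factor: tuple[float, float] = (0.3, 0.9)  # gap/duration when early
    gap_noise_sigma: float = 0.25  # lognormal noise on propensity-scaled gaps
    regimen_switch_prob: float = 0.08
    as_needed_fraction: float = 0.12
    discontinue_prob: float = 0.0  # per-fill chance of a long treatment break
    discontinue_gap_days: tuple[int, int] = (180, 720)
    double_pack_prob: float = 0.15
    dispensing_lag_days: int = 7  # prescription precedes dispensing by <= this
    regimen_library: tuple[RegimenTemplate, ...] = DEFAULT_REGIMEN_LIBRARY

    def __post_init__(self) -> None:
        for name in ("single_fill_fraction", "early_refill_prob",
                     "regimen_switch_prob", "as_needed_fraction", "discontinue_prob"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.min_followup_days <= 0 or self.max_followup_years <= 0:
            raise ValueError("follow-up durations must be positive")
        if self.single_fill_fraction >= 1 and self.n_patients > 0:
            pass  # all-single-fill cohorts are legal, if unusual
        if not self.regimen_library:
            raise ValueError("regimen library must not be empty")


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass
class GroundTruth:
    """Latent generator state for parameter-recovery tests."""

    per_window: pd.DataFrame  # patient_id, granularity, interval_label, true_pdc
    propensity: pd.DataFrame  # patient_id, base_propensity, as_needed, single_fill


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PrescriptionRecord], dict[str, ObservationPeriod], GroundTruth]:
    """Draw a full synthetic cohort: records, periods and ground truth.

    The ground-truth per-window proportion of days covered is computed from
    the generator's own latent supply trace — true regimens, full banking —
    before any text is parsed, so it is independent of the parsing and
    windowing pipeline it is used to validate.
    """
    rng = np.random.default_rng(spec.seed)
    study_span = (spec.study_end - spec.study_start).days + 1
    max_days = int(spec.max_followup_years * 365.25)

    records: list[PrescriptionRecord] = []
    periods: dict[str, ObservationPeriod] = {}
    truth_rows: list[dict] = []
    patient_rows: list[dict] = []

    for i in range(spec.n_patients):
        pid = f"SYN{i:06d}"
        dur = int(
            np.clip(
                spec.max_followup_years * rng.beta(*spec.followup_beta) * 365.25,
                spec.min_followup_days,
                min(max_days, study_span),
            )
        )
        start_offset = rng.integers(0, max(1, study_span - dur + 1))
        p_start = spec.study_start + dt.timedelta(days=int(start_offset))
        p_end = p_start + dt.timedelta(days=dur - 1)
        period = ObservationPeriod(pid, p_start, p_end)
        periods[pid] = period

        if spec.fixed_propensity is not None:
            base_propensity = spec.fixed_propensity
        else:
            base_propensity = float(rng.beta(*spec.propensity_beta))
        as_needed = bool(rng.random() < spec.as_needed_fraction)
        single_fill = bool(rng.random() < spec.single_fill_fraction)

        fills = _simulate_fills(
            rng, spec, period, base_propensity, as_needed, single_fill
        )
        records.extend(_fills_to_records(rng, spec, pid, fills, as_needed))

        covered = _coverage_intervals(fills, period)
        for gran in Granularity:
            for label, window in split_intervals(period, gran):
                lo, hi = window.start_date.toordinal(), window.end_date.toordinal()
                n_cov = sum(
                    max(0, min(hi, b) - max(lo, a) + 1) for a, b in covered
                )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "granularity": gran.value,
                        "interval_label": label,
                        "true_pdc": n_cov / (hi - lo + 1),
                        "n_fills": sum(1 for f in fills if lo <= f.day <= hi),
                    }
                )
        patient_rows.append(
            {
                "patient_id": pid,
                "base_propensity": base_propensity,
                "as_needed": as_needed,
                "single_fill": single_fill,
                "n_fills": len(fills),
            }
        )

    truth = GroundTruth(
        per_window=pd.DataFrame(truth_rows),
        propensity=pd.DataFrame(patient_rows),
    )
    records.sort(key=lambda r: (r.patient_id, r.dispensing_date))
    return records, periods, truth


@dataclass(frozen=True)
class _Fill:
    day: int  # date ordinal
    units: float
    template: RegimenTemplate


def _simulate_fills(
    rng: np.random.Generator,
    spec: CohortSpec,
    period: ObservationPeriod,
    base_propensity: float,
    as_needed: bool,
    single_fill: bool,
) -> list[_Fill]:
    start_ord = period.start_date.toordinal()
    end_ord = period.end_date.toordinal()
    template = spec.regimen_library[rng.integers(len(spec.regimen_library))]

    if single_fill:
        units = template.pack_units * (2 if rng.random() < spec.double_pack_prob else 1)
        return [_Fill(start_ord, units, template)]

    # yearly propensity path: AR(1) around the patient's base level
    mu = _logit(base_propensity)
    z = mu
    year0 = period.start_date.year
    n_years = period.end_date.year - year0 + 1
    propensities = []
    for _ in range(n_years):
        propensities.append(_sigmoid(z))
        z = mu + spec.propensity_rho * (z - mu) + spec.propensity_sigma * rng.normal()
    if spec.fixed_propensity is not None:
        propensities = [spec.fixed_propensity] * n_years

    fills: list[_Fill] = []
    t = start_ord
    while t <= end_ord:
        units = template.pack_units * (2 if rng.random() < spec.double_pack_prob else 1)
        fills.append(_Fill(t, units, template))
        duration = units / template.daily_units
        year_idx = min(dt.date.fromordinal(t).year - year0, n_years - 1)
        pi = max(propensities[year_idx], 1e-3)
        if rng.random() < spec.early_refill_prob:
            gap = duration * rng.uniform(*spec.early_refill_factor)
        else:
            gap = (duration / pi) * math.exp(spec.gap_noise_sigma * rng.normal())
        if as_needed:
            gap *= rng.uniform(0.8, 1.8)
        if rng.random() < spec.discontinue_prob:
            gap += rng.integers(*spec.discontinue_gap_days)
        t += max(1, round(gap))
        if rng.random() < spec.regimen_switch_prob:
            template = spec.regimen_library[rng.integers(len(spec.regimen_library))]
    return fills


def _fills_to_records(
    rng: np.random.Generator,
    spec: CohortSpec,
    pid: str,
    fills: Sequence[_Fill],
    as_needed: bool,
) -> list[PrescriptionRecord]:
    records = []
    for fill in fills:
        text = fill.template.texts[rng.integers(len(fill.template.texts))]
        if as_needed:
            text += _PRN_SUFFIXES[rng.integers(len(_PRN_SUFFIXES))]
        dispensing = dt.date.fromordinal(fill.day)
        lag = int(rng.integers(0, spec.dispensing_lag_days + 1))
        records.append(
            PrescriptionRecord(
                patient_id=pid,
                prescription_date=dispensing - dt.timedelta(days=lag),
                dispensing_date=dispensing,
                medication_name="beclometasone inhaler" if "puff" in text.lower()
                else "montelukast",
                bnf_code="0302000C0",
                formulation="inhaler" if "puff" in text.lower() else "tablet",
                prescribed_quantity=fill.units,
                dispensed_quantity=fill.units,
                dose_text=text,
            )
        )
    return records


def _coverage_intervals(
    fills: Sequence[_Fill], period: ObservationPeriod
) -> list[tuple[int, int]]:
    """Latent day coverage under full banking at the true regimens.

    Walks the fill sequence keeping a running stock; between fills the run
    of covered days has closed form.  Returns closed ordinal intervals
    clipped to the period.
    """
    start_ord = period.start_date.toordinal()
    end_ord = period.end_date.toordinal()
    intervals: list[tuple[int, int]] = []
    level = 0.0
    requirement = 0.0
    t = start_ord
    boundaries = sorted(fills, key=lambda f: f.day)
    for fill in list(boundaries) + [None]:
        boundary = end_ord + 1 if fill is None else fill.day
        if boundary > t:
            if requirement > 0:
                k = min(int(level / requirement + 1e-9), boundary - t)
            else:
                k = 0
            if k > 0:
                lo, hi = max(t, start_ord), min(t + k - 1, end_ord)
                if lo <= hi:
                    if intervals and intervals[-1][1] == lo - 1:
                        intervals[-1] = (intervals[-1][0], hi)
                    else:
                        intervals.append((lo, hi))
                level -= k * requirement
            t = boundary
        if fill is not None:
            level += fill.units
            requirement = fill.template.daily_units
            t = max(t, fill.day)
    return intervals


def scenario_library() -> dict[str, CohortSpec]:
    """Named scenario specs for qualitative and stress testing.

    - ``perfect``: every patient refills exactly on time; all availability
      measures should be 1.
    - ``oversupply``: refills come well before the previous pack runs out,
      driving the quarter-level acquisition measures far above 1.
    - ``gap_and_stop``: frequent long treatment breaks, separating measures
      that stop at the final fill (CMA1/3/5) from those running to the end
      of observation (CMA2/4/6).
    - ``policy_sensitive``: large leftovers (double packs, early refills)
      so the Discard/Cap/Retain policies diverge.
    - ``persistence``: strongly autocorrelated year-to-year propensity, so
      adjacent-year correlation exceeds the two-year-lag correlation.
    """
    base = CohortSpec()
    return {
        "perfect": replace(
            base,
            fixed_propensity=1.0,
            single_fill_fraction=0.0,
            early_refill_prob=0.0,
            gap_noise_sigma=0.0,
            as_needed_fraction=0.0,
            regimen_switch_prob=0.0,
            double_pack_prob=0.0,
        ),
        # short follow-ups: the scenario targets quarter-level refill
        # density, where 3-8x the reference fill rate would otherwise make
        # long histories needlessly heavy
        "oversupply": replace(
            base,
            single_fill_fraction=0.0,
            early_refill_prob=0.85,
            early_refill_factor=(0.25, 0.6),
            as_needed_fraction=0.0,
            followup_beta=(1.0, 1.0),
            max_followup_years=2.0,
        ),
        "gap_and_stop": replace(
            base,
            single_fill_fraction=0.05,
            early_refill_prob=0.2,
            discontinue_prob=0.15,
        ),
        "policy_sensitive": replace(
            base,
            single_fill_fraction=0.0,
            double_pack_prob=0.5,
            early_refill_prob=0.7,
            early_refill_factor=(0.25, 0.7),
        ),
        "persistence": replace(
            base,
            single_fill_fraction=0.0,
            propensity_rho=0.9,
            propensity_sigma=0.35,
            early_refill_prob=0.3,
        ),
    }
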