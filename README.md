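# adheremeter

Medication adherence estimation from prescription dispensing records.

For chronic conditions, routinely collected dispensing data — who collected
which medication, when, how much, and the free-text dose directions — are
the most scalable proxy for adherence available. `adheremeter` turns such
event streams into the eight **Continuous, Multiple-interval Measures of
medication Availability** (CMA1–CMA8), for epidemiologists and health-data
scientists who need adherence estimates per patient, per calendar year and
per calendar quarter, together with the correlation analyses used to choose
among the measures.

## The measures

For a window of `T` days inside a patient's observation period:

- **Acquisition** (CMA1–CMA4): `supply days obtained / T`, where the
  expected supply duration of one dispensing is
  `units / (dose quantity × frequency per day)` — a 60-dose inhaler at two
  puffs twice a day lasts 15 days. CMA1 runs from the first fill to the day
  before the final fill, CMA2 to the end of the period; CMA3 = min(CMA1, 1)
  and CMA4 = min(CMA2, 1). CMA1/CMA2 exceed 1 under oversupply.
- **Availability** (CMA5–CMA8): `days with enough supply in hand / T`, from
  a day-grid simulation in which medication is taken as directed and new
  packs are banked until needed. CMA5/CMA6 share CMA1/CMA2's windows; CMA7
  spans the whole period accounting for stock carried in from earlier
  dispensings; CMA8 starts on the day that starting stock would be
  exhausted. Leftovers at a refill follow one of three carryover policies:
  **Discard** (lost), **Cap** (at most double the new dispensing), or
  **Retain** (all kept), written e.g. `CMA5_D`, `CMA5_C`, `CMA5_R`.

CMA1/3/5 need at least two fills in a window (one refill interval with a
known end); otherwise they are **non-calculable**, a first-class value that
is never conflated with zero. The dose quantity and frequency come from a
rule-based parser of free-text directions ("2 puffs bd prn", "take two
puffs twice daily", …) with editable token tables and configurable
fallbacks.

## Worked example

```python
import datetime as dt
from adheremeter import *

regimen = parse_dose_text("TWO PUFFS TWICE A DAY")
print(f"daily units: {regimen.daily_units}")
print(f"supply duration of a 60-dose inhaler: "
      f"{expected_supply_duration(60, regimen)} days")

period = ObservationPeriod("p1", dt.date(2014, 1, 1), dt.date(2014, 4, 10))
events = [
    SupplyEvent(dt.date(2014, 1, 1), 30, DoseRegimen(1, 1)),   # 30-day pack
    SupplyEvent(dt.date(2014, 3, 2), 30, DoseRegimen(1, 1)),   # refilled day 60
]
timeline = simulate_supply(events, period, CarryoverPolicy.RETAIN)
print(f"available days: {available_days(timeline)} of {period.duration_days}")

dates = [e.date for e in events]
for measure in Measure:
    if measure.needs_prior_history:
        continue
    window = window_for_measure(measure, dates, period)
    value = (cma_acquisition(measure, events, window)
             if measure.is_acquisition
             else cma_availability(measure, timeline, window))
    print(f"{measure.value}: {value:.3f}")
```

prints

```
daily units: 4.0
supply duration of a 60-dose inhaler: 15.0 days
available days: 60 of 100
CMA1: 0.500
CMA2: 0.600
CMA3: 0.500
CMA4: 0.600
CMA5: 0.500
CMA6: 0.600
```

The patient held 30 days of supply, waited 30 days, refilled, and the
period ran 40 more days: over the 60-day refill interval half the days were
covered (CMA1 = CMA5 = 0.5); over the 100-day period 60 of 100 days were
covered (CMA2 = CMA6 = 0.6). With a single fill per interval the three
carryover policies coincide.

Cohort-scale work goes through the pipeline and CLI:

```sh
adheremeter simulate --scenario oversupply --n 1000 --seed 42 --out cohort.csv
adheremeter estimate --records cohort.csv --periods cohort_periods.csv --out est.csv
adheremeter correlate --estimates est.csv --granularity quarter --out corr.csv
```

`estimate_cohort` produces a long-format table of
(patient, interval, measure, policy) estimates at full-follow-up, yearly
and quarterly granularity, applying the calculability rules (CMA7/8 are
omitted from each patient's first year and quarter, where no prior history
exists); `adjacent_interval_correlations` and
`within_interval_correlations` provide the Spearman persistence and
measure-comparison analyses. See `docs/methods.md` for the full model
description.

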