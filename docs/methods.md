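# Methods

## The estimation problem

Routine prescribing/dispensing data record *when* a patient collected
medication, *how much*, and the free-text directions for taking it. From
these three ingredients one can estimate adherence — how closely collection
behaviour tracks the directed regimen — without any direct observation of
medication taking. `adheremeter` implements the family of eight Continuous,
Multiple-interval Measures of medication Availability (CMA1–CMA8, after
Vollmer and colleagues), extended with an explicit treatment of leftover
supply when a new prescription arrives.

## Expected supply duration and dose-text parsing

The expected duration of one dispensing is

    duration (days) = dispensed units / (dose quantity × frequency per day)

so a 60-dose inhaler directed at two puffs twice a day lasts 15 days.
Durations are kept fractional; whole-day semantics enter only on the supply
engine's day grid.

Dose quantity and frequency are extracted from the free-text directions by
a rule-based parser over editable token tables
(`src/adheremeter/data/dose_rules.yaml`): number words one–twelve (digits
unlimited), administration-unit words (puff/dose/tablet/…), frequency
phrases ("twice a day", "every morning and night", …) and Latin
abbreviations (od/bd/tds/qds → 1/2/3/4 per day). As-needed tokens (prn, "as
required", …) set a flag but do not suppress the nominal regimen: for such
patients the measures are read as usage-pattern proxies rather than
adherence to a fixed schedule, and downstream consumers can filter on the
flag. Deliberate choices, configurable where noted:

- **Ranges** ("1–2 puffs") resolve to the **maximum** by default
  (`RangePolicy`): under-reading the directed dose inflates apparent
  oversupply, so the top of the range is the conservative choice for
  adherence estimation.
- An explicit frequency with no numeral ("take twice daily") reads as one
  unit per administration, the standard dispensing convention.
- Parse failures are values with a reason category (`no-quantity`,
  `no-frequency`, `empty`), never exceptions; the pipeline counts them and
  falls back to a formulation-keyed default regimen (shipped default: 2
  units twice daily, the modal controller-inhaler direction). Records with
  neither a parse nor a default are flagged non-analysable and skipped.
- The shipped rule tables are a reconstruction of the vocabulary of UK
  primary-care dose directions for inhaled therapies, not an exhaustive
  inventory; they are data files precisely so they can be extended.

## The supply engine

Supply is tracked in dose units on a day grid. A day is **available** iff
the stock at the start of the day covers one full day's requirement, in
which case that requirement is consumed; dispensings arrive at the start of
their day and are banked until needed. Same-day dispensings are condensed
into one event by summing units (the condensed event carries the last
record's regimen). Three carryover policies govern leftovers at a new
dispensing of `u` units when `l` units remain:

| policy  | level after event |
|---------|-------------------|
| DISCARD | `u`               |
| CAP     | `min(l + u, 2u)`  |
| RETAIN  | `l + u`           |

The regimen of the most recent dispensing governs consumption from its date
forward — regimen changes are immediate, and a medication change does not
bin existing stock (stock and regimen are deliberately decoupled). Partial
leftovers smaller than a day's requirement persist; they can become usable
if a later regimen lowers the daily requirement. The cap applies at event
instants only, reading "maximum available after a dispensing" literally.

Although the semantics are per-day, the implementation is event-driven:
between events the requirement is constant, so the run of available days is
`min(floor(level / requirement), segment length)` and the residual follows
in closed form. This makes simulation O(events) instead of O(days). A
deliberately naive one-day-at-a-time reference implementation lives in the
test-suite (`tests/naive_oracle.py`); the two are compared exactly (integer
units keep both routes in exact arithmetic) on thousands of randomised
instances.

### A note on policy monotonicity

Total available days over a fixed window satisfy DISCARD ≤ CAP ≤ RETAIN,
and the property suite asserts exactly that for CMA5–7. The *day-set*
version of the claim (every day available under DISCARD is available under
CAP, etc.) is **false** in general: a sub-day residual can survive under
CAP on a day RETAIN already spent, and after the next fill `min(l + u, 2u)`
can exceed the RETAIN level, or a regimen reduction can make the residual
usable. CMA8 is excluded from the unconditional ordering because its window
*start* (stock-exhaustion day) is itself policy-dependent; with different
denominators the ratios need not be ordered. The tests compare CMA8 across
policies only when the three windows coincide.

## Analysis windows and the eight measures

Within an observation period (closed date interval) the window of each
measure is:

| measure | start | end | numerator |
|---|---|---|---|
| CMA1/CMA3 | first fill | day before final fill | supply days obtained |
| CMA2/CMA4 | first fill | period end | supply days obtained |
| CMA5 | first fill | day before final fill | days available |
| CMA6 | first fill | period end | days available |
| CMA7 | period start | period end | days available (with prior stock) |
| CMA8 | initial-stock exhaustion day | period end | days available |

all divided by the closed window duration; CMA3/CMA4 clamp CMA1/CMA2 at 1.
A fill is in-window iff its dispensing date lies in the closed window, so
the final fill is excluded from the CMA1/3/5 numerators by construction.
The CMA1-family duration equals final-fill date minus first-fill date (the
standard refill-interval denominator); a single fill makes that window
empty, which is why CMA1/3/5 require at least two fills. **Non-calculable
is a first-class value** (NaN in tables, empty field in CSV), never zero —
single-fill windows are common in routine data and conflating them with
zero adherence would corrupt every distribution.

CMA8's exhaustion day draws down the stock held at the window start at the
prevailing daily requirement (updated immediately by in-window regimen
changes) while in-window acquisitions are banked. How DISCARD should
interact with that draw-down is genuinely underdetermined; the default
banks regardless of policy, and `discard_resets_exhaustion=True` instead
wipes the starting stock at the first in-window dispensing of a DISCARD
timeline.

## Pipeline rules

Estimates are produced at three granularities: the full follow-up, calendar
years, and calendar quarters (anniversary alignment behind a flag). Year
and quarter windows tile the observation period exactly; the per-window
"observation period" fed to the measure definitions is the window itself.
Additional rules:

- CMA7/CMA8 need prior history to price the starting stock, so they are
  omitted for each patient's first year and first quarter; prior events for
  a later window are all of the patient's earlier in-period events,
  simulated under the same policy (operationally: the window is read off
  one full-period timeline per policy). For the full follow-up they are
  computed with zero prior stock (no carryover into the study), making
  full-window CMA7 = CMA8.
- CMA5/CMA6 in a year/quarter window use a fresh zero-stock simulation of
  the in-window events, per their definitions.
- A follow-up of zero days (single fill on the final observation day, a
  real pattern in registry data) yields all measures non-calculable.
- Observation periods come from a companion table or default to
  [first dispensing, study end].

## Correlation analyses

Spearman rank correlation (average ranks for ties, t-approximation
p-values) is computed (a) for one measure between a window and the window
1 or 2 intervals later within patients, and (b) between all 16
measure/policy variants matched by (patient, interval), pairwise-complete.
Coefficients classify as weak (|R| ≤ 0.3), moderate (0.3 < |R| ≤ 0.7) or
strong (|R| > 0.7); the printed class definitions overlap at the
boundaries, resolved here by assigning boundary values to the lower class.

## The synthetic-data generator

The generator emulates a long-running controller-therapy cohort: follow-up
drawn as 8.2 years × Beta(0.93, 0.35) (median ≈ 7 y, IQR ≈ 4.3–8.0 y,
matched once by quantile fitting to the reference cohort's summary), a
16.7% single-fill patient fraction, latent adherence propensity ~
Beta(3.5, 1.5) evolving year-to-year as an AR(1) on the logit scale
(ρ = 0.7, σ = 0.5), refill gaps of `duration / propensity` with lognormal
noise, a 45% chance of an early refill (gap = 0.3–0.9 × duration,
producing oversupply at roughly the rate seen in dispensing data), 8%
regimen switches per fill, 12% as-needed patients, and a 15% double-pack
chance. Dose texts are sampled as raw strings — including messy variants —
so the parser is exercised end-to-end rather than bypassed.

Ground truth: each patient's latent day-coverage trace (full banking at the
*true* regimens, computed inside the generator independently of the
production engine) is aggregated per window into a true proportion of days
covered. Full-pipeline CMA6 (retain) recovers it with Spearman ≈ 1 at the
full-follow-up level, which simultaneously validates parsing, condensing,
simulation and windowing. At the year level agreement is deliberately lower
(≈ 0.74): year-window CMA6 starts at the first in-year fill with zero
prior stock while the latent truth counts carried-in coverage from January
1 — a real difference between the measure and latent coverage, not an
implementation gap (year-level CMA7, whose window and carryover match the
truth's, recovers it at ≈ 1).

What the generator does *not* emulate: primary non-adherence (uncollected
prescriptions are unobservable in dispensing-only data), within-day dose
timing, genuine medication-taking behaviour distinct from collection,
practice-level or seasonal effects, and linkage noise between prescribing
and dispensing feeds. Passing tests therefore demonstrate correctness of
the estimator arithmetic and its contracts on realistic event streams, not
the clinical validity of any one measure on real records.

Scenario specs (`scenario_library()`) are stress fixtures, not cohort
emulations: `perfect`, `oversupply` (short follow-ups — up to 2 years —
since it targets quarter-level refill density at 3–8× the reference rate),
`gap_and_stop`, `policy_sensitive`, and `persistence`.

## Numerical choices and problem sizes

- Day arithmetic uses date ordinals (integers); floor divisions guard
  against float noise with a 1e-9 epsilon. Engine-vs-oracle comparisons use
  integer units so both routes are exact.
- Randomised property suites use fixed seeds (hypothesis derandomised);
  scenario checks run at n = 10,000 patients, engine cross-checks at 1,000
  random instances of ≤ 10 events over ≤ 400 days — sizes at which every
  Monte-Carlo margin in the tests is ≥ 10× its sampling error.
- Quantiles use the linear-interpolation default of `numpy.percentile`.

## Known limitations

- The parser covers fixed daily schedules; meal-relative timing ("after
  food") and non-inhaled delivery verbs ("inject", "apply") are out of
  scope, as is any statistical/ML text parsing.
- No persistence/discontinuation episode detection; gaps influence the
  measures but are not segmented into intermission episodes.
- No linkage of clinical outcomes, and no screening of medication records
  by indication.
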