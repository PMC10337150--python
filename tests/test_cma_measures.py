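import math

import numpy as np
import pytest

from adheremeter import (
    CarryoverPolicy,
    Measure,
    ObservationPeriod,
    cma_acquisition,
    cma_availability,
    simulate_supply,
    supply_days_obtained,
    supply_exhaustion_date,
    window_for_measure,
)
from conftest import day, event, to_engine_events
from naive_oracle import naive_cma_values, random_instance

R = CarryoverPolicy.RETAIN


@pytest.fixture
def two_fill_case(period_100):
    """Fills on days 0 and 60, 30 days' supply each, 100-day period."""
    events = [event(0, 30), event(60, 30)]
    return events, [e.date for e in events], period_100


# --- windows ---------------------------------------------------------------

def test_window_rules(two_fill_case):
    events, dates, period = two_fill_case
    w1 = window_for_measure(Measure.CMA1, dates, period)
    assert (w1.start_date, w1.end_date) == (day(0), day(59))
    w2 = window_for_measure(Measure.CMA2, dates, period)
    assert (w2.start_date, w2.end_date) == (day(0), day(99))
    w7 = window_for_measure(Measure.CMA7, dates, period)
    assert (w7.start_date, w7.end_date) == (period.start_date, period.end_date)


def test_single_fill_gives_empty_window_for_cma135(period_100):
    for measure in (Measure.CMA1, Measure.CMA3, Measure.CMA5):
        assert window_for_measure(measure, [day(10)], period_100) is None


def test_cma8_window_empty_when_exhaustion_beyond_period(period_100):
    late = day(150)
    assert window_for_measure(Measure.CMA8, [day(0)], period_100, late) is None


def test_cma8_requires_exhaustion_date(period_100):
    with pytest.raises(ValueError):
        window_for_measure(Measure.CMA8, [day(0)], period_100)


# --- supply days obtained --------------------------------------------------

def test_supply_days_additive(two_fill_case):
    events, dates, period = two_fill_case
    w = window_for_measure(Measure.CMA2, dates, period)
    assert supply_days_obtained(events, w) == 60


def test_supply_days_worked_example(period_100):
    events = [event(0, 60, 2, 2)]
    w = window_for_measure(Measure.CMA2, [day(0)], period_100)
    assert supply_days_obtained(events, w) == 15


def test_fill_outside_window_contributes_nothing(two_fill_case):
    events, dates, period = two_fill_case
    w1 = window_for_measure(Measure.CMA1, dates, period)  # ends day 59
    assert supply_days_obtained(events, w1) == 30  # final fill excluded


# --- acquisition measures --------------------------------------------------

def test_acquisition_worked_example(two_fill_case):
    events, dates, period = two_fill_case
    expected = {Measure.CMA1: 0.5, Measure.CMA2: 0.6,
                Measure.CMA3: 0.5, Measure.CMA4: 0.6}
    for measure, value in expected.items():
        w = window_for_measure(measure, dates, period)
        assert cma_acquisition(measure, events, w) == pytest.approx(value)


def test_cma3_clamps_oversupply(period_100):
    # 10 fills of 30 days, 10 days apart: CMA1 far above 1
    events = [event(10 * k, 30) for k in range(10)]
    dates = [e.date for e in events]
    w = window_for_measure(Measure.CMA1, dates, period_100)
    cma1 = cma_acquisition(Measure.CMA1, events, w)
    assert cma1 > 2
    assert cma_acquisition(Measure.CMA3, events, w) == 1.0


def test_acquisition_non_calculable_on_empty_window(period_100):
    value = cma_acquisition(Measure.CMA1, [], None)
    assert math.isnan(value)


# --- availability measures -------------------------------------------------

def test_availability_worked_example(two_fill_case, policy):
    events, dates, period = two_fill_case
    timeline = simulate_supply(events, period, policy)
    w5 = window_for_measure(Measure.CMA5, dates, period)
    w6 = window_for_measure(Measure.CMA6, dates, period)
    assert cma_availability(Measure.CMA5, timeline, w5) == pytest.approx(0.5)
    assert cma_availability(Measure.CMA6, timeline, w6) == pytest.approx(0.6)


def test_cma7_cma8_with_prior_stock(period_100):
    """10 days of carried-in stock plus a 30-day fill on day 5 (RETAIN):
    CMA7 = 40/100, CMA8 window opens at day 10 with value 30/90."""
    prior = [event(-20, 30)]
    events = [event(5, 30)]
    timeline = simulate_supply(events, period_100, R, prior_events=prior)
    w7 = window_for_measure(Measure.CMA7, [day(5)], period_100)
    assert cma_availability(Measure.CMA7, timeline, w7) == pytest.approx(0.40)
    exhaustion = supply_exhaustion_date(timeline, events=events)
    assert exhaustion == day(10)
    w8 = window_for_measure(Measure.CMA8, [day(5)], period_100, exhaustion)
    assert cma_availability(Measure.CMA8, timeline, w8) == pytest.approx(30 / 90)


def test_full_coverage_gives_ones(period_100, policy):
    events = [event(25 * k, 25) for k in range(4)]
    dates = [e.date for e in events]
    timeline = simulate_supply(events, period_100, policy)
    for measure in (Measure.CMA5, Measure.CMA6):
        w = window_for_measure(measure, dates, period_100)
        assert cma_availability(measure, timeline, w) == 1.0
    w7 = window_for_measure(Measure.CMA7, dates, period_100)
    assert cma_availability(Measure.CMA7, timeline, w7) == 1.0


def test_availability_non_calculable_on_empty_window(period_100):
    timeline = simulate_supply([], period_100, R)
    assert math.isnan(cma_availability(Measure.CMA5, timeline, None))


# --- invariants ------------------------------------------------------------

def test_clamp_identities_on_random_instances():
    """CMA3 = min(CMA1, 1) and CMA4 = min(CMA2, 1) identically."""
    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(300):
        triples, (lo, hi) = random_instance(rng, max_events=8, max_days=300)
        if len(triples) < 2:
            continue
        period = ObservationPeriod("p", lo, hi)
        events = to_engine_events(triples)
        dates = [e.date for e in events]
        w13 = window_for_measure(Measure.CMA1, dates, period)
        w24 = window_for_measure(Measure.CMA2, dates, period)
        cma1 = cma_acquisition(Measure.CMA1, events, w13)
        cma2 = cma_acquisition(Measure.CMA2, events, w24)
        assert cma_acquisition(Measure.CMA3, events, w13) == min(cma1, 1.0)
        assert cma_acquisition(Measure.CMA4, events, w24) == min(cma2, 1.0)
        checked += 1
    assert checked > 100


def test_availability_measures_bounded_and_match_oracle():
    """CMA5-8 in [0,1] and equal to the naive day-walk values."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        triples, (lo, hi) = random_instance(rng, max_events=6, max_days=250)
        period = ObservationPeriod("p", lo, hi)
        events = to_engine_events(triples)
        dates = sorted({e.date for e in events})
        for pol in CarryoverPolicy:
            timeline = simulate_supply(events, period, pol)
            oracle = naive_cma_values(triples, period, pol.value)
            for measure in (Measure.CMA5, Measure.CMA6):
                w = window_for_measure(measure, dates, period)
                value = cma_availability(measure, timeline, w)
                if oracle[measure.value] is None:
                    assert math.isnan(value)
                else:
                    assert value == oracle[measure.value]
                    assert 0 <= value <= 1
            w7 = window_for_measure(Measure.CMA7, dates, period)
            assert cma_availability(Measure.CMA7, timeline, w7) == oracle["CMA7"]


def test_back_to_back_fills_make_cma1_and_cma5_one(period_100):
    """Each fill consumed exactly when the next arrives: CMA1 = CMA5 = 1
    and CMA2 = CMA6."""
    events = [event(0, 20), event(20, 20), event(40, 20)]
    dates = [e.date for e in events]
    timeline = simulate_supply(events, period_100, R)
    w1 = window_for_measure(Measure.CMA1, dates, period_100)
    w2 = window_for_measure(Measure.CMA2, dates, period_100)
    assert cma_acquisition(Measure.CMA1, events, w1) == 1.0
    assert cma_availability(Measure.CMA5, timeline, w1) == 1.0
    cma2 = cma_acquisition(Measure.CMA2, events, w2)
    assert cma_availability(Measure.CMA6, timeline, w2) == pytest.approx(cma2)


def test_oversupply_separates_acquisition_from_availability(period_100):
    """Refill interval shorter than supply duration: CMA1 > 1, CMA5 <= 1."""
    events = [event(15 * k, 30) for k in range(5)]  # 30-day packs every 15 days
    dates = [e.date for e in events]
    w1 = window_for_measure(Measure.CMA1, dates, period_100)
    assert cma_acquisition(Measure.CMA1, events, w1) > 1
    timeline = simulate_supply(events, period_100, R)
    assert cma_availability(Measure.CMA5, timeline, w1) <= 1
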