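import datetime as dt

import pytest

from adheremeter import (
    CarryoverPolicy,
    DoseRegimen,
    ObservationPeriod,
    PrescriptionRecord,
    SupplyEvent,
)

BASE = dt.date(2014, 1, 1)


def day(k: int) -> dt.date:
    return BASE + dt.timedelta(days=k)


def make_record(pid="p1", disp=0, qty=60.0, text="TWO PUFFS TWICE A DAY", **kw):
    defaults = dict(
        patient_id=pid,
        prescription_date=day(disp),
        dispensing_date=day(disp),
        medication_name="beclometasone inhaler",
        bnf_code="0302000C0",
        formulation="inhaler",
        prescribed_quantity=qty,
        dispensed_quantity=qty,
        dose_text=text,
    )
    defaults.update(kw)
    return PrescriptionRecord(**defaults)


def event(k: int, units: float, dose=1.0, freq=1.0) -> SupplyEvent:
    return SupplyEvent(day(k), units, DoseRegimen(dose, freq))


@pytest.fixture
def period_100():
    """100-day observation period starting at the base date."""
    return ObservationPeriod("p1", day(0), day(99))


@pytest.fixture(params=list(CarryoverPolicy), ids=[p.name for p in CarryoverPolicy])
def policy(request):
    return request.param


def to_engine_events(triples):
    """(date, units, requirement) triples -> SupplyEvents with a 1 x req/day
    regimen (requirement carried entirely by the frequency)."""
    return [
        SupplyEvent(date, float(units), DoseRegimen(1.0, float(req)))
        for date, units, req in triples
    ]
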