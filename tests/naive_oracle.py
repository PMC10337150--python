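"""Deliberately naive reference implementations used as independent oracles.

Everything here walks the day grid one day at a time (or ranks by hand) and
is kept structurally unrelated to the production code so the two routes can
disagree if either is wrong.  Instances are built with integer units and
integer daily requirements so both routes stay in exactly representable
arithmetic and can be compared exactly.
"""

from __future__ import annotations

import datetime as dt


def naive_timeline(events, period, policy, prior_events=None):
    """One-day-at-a-time supply walk.

    ``events``/``prior_events``: iterables of (date, units, daily_requirement)
    triples.  ``policy`` is "D", "C" or "R".  Returns (available, levels):
    per-day lists over the closed period, levels taken at the start of each
    day after any dispensing.
    """
    by_day: dict[int, list[tuple[float, float]]] = {}
    for date, units, req in list(prior_events or []) + list(events):
        by_day.setdefault(date.toordinal(), []).append((units, req))

    start = period.start_date.toordinal()
    end = period.end_date.toordinal()
    sim_start = min([start] + list(by_day))

    level = 0.0
    requirement = 0.0
    available, levels = [], []
    for day in range(sim_start, end + 1):
        for units, req in by_day.get(day, []):
            if policy == "D":
                level = units
            elif policy == "C":
                level = min(level + units, 2 * units)
            else:
                level = level + units
            requirement = req
        in_period = day >= start
        if in_period:
            levels.append(level)
        if requirement > 0 and level >= requirement:
            if in_period:
                available.append(True)
            level -= requirement
        elif in_period:
            available.append(False)
    return available, levels


def naive_available_days(available, period, window):
    start = period.start_date.toordinal()
    lo = window[0].toordinal() - start
    hi = window[1].toordinal() - start
    return sum(1 for i in range(lo, hi + 1) if available[i])


def naive_exhaustion_day(stock, requirement_by_day, period):
    """First day the starting stock cannot cover a full day's requirement;
    in-period acquisitions are banked (ignored)."""
    day = period.start_date.toordinal()
    end = period.end_date.toordinal()
    while day <= end + 1:
        req = requirement_by_day(day)
        if req > 0 and stock < req:
            return dt.date.fromordinal(day)
        if req > 0:
            stock -= req
        day += 1
    return dt.date.fromordinal(end + 2)


def naive_cma_values(events, period, policy):
    """CMA5-CMA8 computed from the naive day walk, mirroring the window
    rules from first principles.  Returns dict measure -> value or None."""
    available, _ = naive_timeline(events, period, policy)
    start = period.start_date.toordinal()
    end = period.end_date.toordinal()
    dates = sorted({d for d, _, _ in events})
    out = {}

    # CMA5: [first fill, day before final fill]
    if len(dates) >= 2:
        lo, hi = dates[0].toordinal(), dates[-1].toordinal() - 1
        n = sum(1 for i in range(lo - start, hi - start + 1) if available[i])
        out["CMA5"] = n / (hi - lo + 1)
    else:
        out["CMA5"] = None

    # CMA6: [first fill, end of period]
    if dates:
        lo = dates[0].toordinal()
        n = sum(1 for i in range(lo - start, end - start + 1) if available[i])
        out["CMA6"] = n / (end - lo + 1)
    else:
        out["CMA6"] = None

    # CMA7: whole period (zero prior stock here)
    out["CMA7"] = sum(available) / (end - start + 1)

    # CMA8 with zero prior stock: exhaustion at period start, whole period
    out["CMA8"] = out["CMA7"]
    return out


def naive_spearman(x, y):
    """Rank correlation via hand-computed average ranks + Pearson formula."""
    pairs = [(a, b) for a, b in zip(x, y) if a == a and b == b]
    n = len(pairs)
    if n < 2:
        return float("nan")

    def ranks(values):
        order = sorted(range(n), key=lambda i: values[i])
        out = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                out[order[k]] = avg
            i = j + 1
        return out

    rx = ranks([p[0] for p in pairs])
    ry = ranks([p[1] for p in pairs])
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / (vx * vy) ** 0.5


def random_instance(rng, max_events=10, max_days=400):
    """Random small integer-valued instance for engine cross-checks.

    Returns (events, period) with events as (date, units, requirement)
    triples; all quantities integral so day-walk and closed-form arithmetic
    agree exactly.
    """
    base = dt.date(2012, 1, 1)
    n_days = int(rng.integers(10, max_days + 1))
    period_start = base
    period_end = base + dt.timedelta(days=n_days - 1)
    n_events = int(rng.integers(0, max_events + 1))
    days = sorted(rng.choice(n_days, size=n_events, replace=False)) if n_events else []
    events = []
    for day in days:
        units = int(rng.integers(1, 301))
        req = int(rng.integers(1, 5)) * int(rng.integers(1, 4))
        events.append((base + dt.timedelta(days=int(day)), units, req))
    return events, (period_start, period_end)
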