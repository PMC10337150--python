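"""Spearman correlation analyses over the cohort estimate table.

Two analyses are supported: correlation of each measure with itself in
chronologically adjacent intervals (persistence of adherence, lag 1 or 2),
and the pairwise correlation matrix of all measure/policy variants matched
by interval.  Pairs with a non-calculable member are dropped pairwise
(pairwise-complete, not listwise).  Coefficients are classified as weak
(|R| <= 0.3), moderate (0.3 < |R| <= 0.7) or strong (|R| > 0.7); boundary
values fall to the lower class.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cma_measures import Measure
from .pipeline import Granularity
from .supply_engine import CarryoverPolicy

#: measure/policy variant labels in canonical display order
VARIANT_ORDER = (
    "CMA1", "CMA2", "CMA3", "CMA4",
    "CMA5_D", "CMA5_C", "CMA5_R",
    "CMA6_D", "CMA6_C", "CMA6_R",
    "CMA7_D", "CMA7_C", "CMA7_R",
    "CMA8_D", "CMA8_C", "CMA8_R",
)


def classify_strength(coefficient: float) -> str:
    """weak (|R| <= 0.3) / moderate (0.3 < |R| <= 0.7) / strong (|R| > 0.7)."""
    r = abs(coefficient)
    if r > 0.7:
        return "strong"
    if r > 0.3:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    coefficient: float
    n_pairs: int
    p_value: float = float("nan")

    @property
    def strength(self) -> str:
        return classify_strength(self.coefficient)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing (NaN) member are dropped first.  Returns
    (coefficient, p-value, n complete pairs); with fewer than two complete
    pairs or zero rank variance the coefficient is NaN, not an exception.
    The p-value uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def variant_label(measure: Measure | str, policy: CarryoverPolicy | str | None) -> str:
    measure = getattr(measure, "value", measure)
    policy = getattr(policy, "value", policy) or ""
    return f"{measure}_{policy}" if policy else measure


def _interval_ordinal(label: str, granularity: Granularity) -> int:
    """Map an interval label to a consecutive integer so that adjacent
    intervals differ by exactly one."""
    if granularity is Granularity.YEAR:
        m = re.fullmatch(r"(\d{4})|Y(\d+)", label)
        if not m:
            raise ValueError(f"unrecognised year label {label!r}")
        return int(m.group(1) or m.group(2))
    m = re.fullmatch(r"(\d{4})Q([1-4])|Q(\d+)", label)
    if not m:
        raise ValueError(f"unrecognised quarter label {label!r}")
    if m.group(3):
        return int(m.group(3))
    return 4 * int(m.group(1)) + int(m.group(2)) - 1


def adjacent_interval_correlations(
    table: pd.DataFrame,
    measure: Measure | str,
    policy: CarryoverPolicy | str | None,
    granularity: Granularity | str,
    lag: int = 1,
) -> CorrelationResult:
    """Correlation of one measure between interval t and interval t+lag.

    Pairs are formed within patients for every pair of windows ``lag``
    intervals apart in which the measure was calculable for both.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    granularity = Granularity(getattr(granularity, "value", granularity))
    if granularity is Granularity.FULL:
        raise ValueError("adjacent-interval correlation needs year or quarter windows")
    measure = getattr(measure, "value", measure)
    policy_code = getattr(policy, "value", policy) or ""

    sub = table[
        (table["measure"] == measure)
        & (table["policy"] == policy_code)
        & (table["granularity"] == granularity.value)
    ].dropna(subset=["value"])
    if sub.empty:
        return CorrelationResult(f"{variant_label(measure, policy_code)} lag{lag}",
                                 float("nan"), 0)

    ordinals = sub["interval_label"].map(lambda s: _interval_ordinal(s, granularity))
    keyed = pd.Series(
        sub["value"].to_numpy(),
        index=pd.MultiIndex.from_arrays([sub["patient_id"], ordinals]),
    )
    shifted_index = pd.MultiIndex.from_arrays(
        [sub["patient_id"], ordinals + lag]
    )
    later = keyed.reindex(shifted_index)
    rho, p, n = spearman(keyed.to_numpy(), later.to_numpy())
    return CorrelationResult(
        f"{variant_label(measure, policy_code)} lag{lag}", rho, n, p
    )


def within_interval_correlations(
    table: pd.DataFrame,
    granularity: Granularity | str,
) -> pd.DataFrame:
    """Pairwise-complete Spearman matrix of all measure/policy variants,
    matched by (patient, interval)."""
    granularity = Granularity(getattr(granularity, "value", granularity))
    sub = table[table["granularity"] == granularity.value].copy()
    sub["variant"] = [
        variant_label(m, p) for m, p in zip(sub["measure"], sub["policy"])
    ]
    wide = sub.pivot_table(
        index=["patient_id", "interval_label"],
        columns="variant",
        values="value",
        aggfunc="first",
    )
    order = [v for v in VARIANT_ORDER if v in wide.columns]
    extra = [v for v in wide.columns if v not in VARIANT_ORDER]
    wide = wide[order + extra]
    return wide.corr(method="spearman", min_periods=2)


def plot_correlation_heatmap(matrix: pd.DataFrame, path=None, title: str = ""):
    """Heatmap of a within-interval correlation matrix (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdYlGn")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            v = matrix.iat[i, j]
            if not math.isnan(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
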