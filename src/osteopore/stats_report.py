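"""Per-animal aggregation, two-group comparison, boxplot summaries.

Each animal contributes one value per metric (measurements averaged per
animal); groups are compared with the unpaired two-tailed Student's t-test
(pooled variance, df = n1 + n2 − 2), significant at p < 0.05.  No
multiple-testing correction is applied — a documented limitation.  Boxplot
summaries follow the convention: whiskers at data min/max (no outlier
fencing), box at the 25th/75th percentiles (linear interpolation), line at
the median, dot at the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "aggregate_per_animal",
    "students_t",
    "boxplot_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSummary:
    min: float
    q25: float
    median: float
    q75: float
    max: float
    mean: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: int
    p_value: float
    significant: bool


def aggregate_per_animal(
    measurements: Iterable[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Average repeated measurements per animal; order of first appearance."""
    measurements = list(measurements)
    if not measurements:
        raise InputError("no measurements to aggregate")
    df = pd.DataFrame(measurements, columns=["animal_id", "value"])
    means = df.groupby("animal_id", sort=False)["value"].mean()
    return list(means.items())


def students_t(
    group1: Sequence[float], group2: Sequence[float], alpha: float = 0.05
) -> TTestResult:
    """Unpaired two-tailed Student's (equal-variance) t-test.

    Pooled SD with df = n1 + n2 − 2.  Two identical-constant groups (zero
    pooled variance, equal means) return t = 0, p = 1.
    """
    a = np.asarray(group1, dtype=np.float64)
    b = np.asarray(group2, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    df = a.size + b.size - 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    pooled_var = ss / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, False)
        raise InputError("zero pooled variance with unequal means")
    se = math.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p), bool(p < alpha))


def boxplot_summary(values: Sequence[float]) -> GroupSummary:
    """Min/quartile/max/mean summary matching the figures' boxplot convention."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise InputError("empty value list")
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        min=float(v.min()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        max=float(v.max()),
        mean=float(v.mean()),
        n=int(v.size),
    )


def compare_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    metric: str = "",
    alpha: float = 0.05,
) -> dict:
    """Boxplot summaries plus t-test for one metric, as a JSON-ready dict."""
    from dataclasses import asdict

    return {
        "metric": metric,
        "group1": asdict(boxplot_summary(group1)),
        "group2": asdict(boxplot_summary(group2)),
        "t_test": asdict(students_t(group1, group2, alpha=alpha)),
    }
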