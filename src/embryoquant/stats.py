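"""Two-group summary statistics shared by every measurement module.

The reporting convention throughout the package is mean ± SEM per group with
a two-sample Student's t test (pooled variance) and star annotations:
``*`` for p ≤ 0.05 and ``**`` for p ≤ 0.01.  Welch's unequal-variance test is
available behind a flag but is not the default.  No multiple-testing
correction is applied; output metadata says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "GroupComparison",
    "mean_sem",
    "two_sample_t",
    "stars_for",
    "compare",
    "comparison_frame",
]


@dataclass(frozen=True)
class GroupComparison:
    """Tidy record of one two-group comparison.

    SEM is the sample standard deviation (n−1 denominator) over √n.
    ``stars`` follows the figure-legend rule: ``"*"`` iff 0.01 < p ≤ 0.05,
    ``"**"`` iff p ≤ 0.01, else ``""``.
    """

    metric: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: float
    p: float
    stars: str
    correction: str = "none"


def _clean(values: Iterable[float], drop_nan: bool) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float).ravel()
    if drop_nan:
        arr = arr[~np.isnan(arr)]
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    return arr


def mean_sem(values: Iterable[float], *, drop_nan: bool = False) -> tuple[float, float, int]:
    """Sample mean, standard error of the mean (sd/√n) and n.

    Requires n ≥ 2 so the n−1 variance denominator is defined.
    """
    arr = _clean(values, drop_nan)
    n = arr.size
    if n < 2:
        raise ValueError(f"mean_sem requires n >= 2, got n={n}")
    sd = float(np.std(arr, ddof=1))
    return float(np.mean(arr)), sd / math.sqrt(n), n


def two_sample_t(
    a: Iterable[float],
    b: Iterable[float],
    *,
    welch: bool = False,
    drop_nan: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test; classical pooled-variance Student by default.

    Returns ``(t, df, p)`` with a two-sided p value.  With pooled variance,
    df = nA + nB − 2.  If the pooled variance is zero the test is degenerate:
    equal means give (0, df, 1); unequal means are rejected because the t
    statistic is unbounded.
    """
    xa = _clean(a, drop_nan)
    xb = _clean(b, drop_nan)
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError(f"two_sample_t requires n >= 2 per group, got {na} and {nb}")
    ma, mb = float(np.mean(xa)), float(np.mean(xb))
    va, vb = float(np.var(xa, ddof=1)), float(np.var(xb, ddof=1))
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            if ma == mb:
                return 0.0, float(na + nb - 2), 1.0
            raise ValueError("degenerate variance: zero variance with unequal means")
        t = (ma - mb) / math.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        if pooled == 0.0:
            if ma == mb:
                return 0.0, df, 1.0
            raise ValueError("degenerate variance: zero pooled variance with unequal means")
        t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def stars_for(p: float) -> str:
    """Figure-legend significance annotation: ** for p≤0.01, * for p≤0.05."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare(
    metric: str,
    a: Iterable[float],
    b: Iterable[float],
    *,
    welch: bool = False,
    drop_nan: bool = False,
) -> GroupComparison:
    """Assemble the full two-group comparison for one metric."""
    xa = _clean(a, drop_nan)
    xb = _clean(b, drop_nan)
    mean_a, sem_a, n_a = mean_sem(xa)
    mean_b, sem_b, n_b = mean_sem(xb)
    t, df, p = two_sample_t(xa, xb, welch=welch)
    return GroupComparison(
        metric=metric,
        mean_a=mean_a, sem_a=sem_a, n_a=n_a,
        mean_b=mean_b, sem_b=sem_b, n_b=n_b,
        t=t, df=df, p=p, stars=stars_for(p),
    )


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy DataFrame, one row per comparison."""
    return pd.DataFrame([asdict(c) for c in comparisons])
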