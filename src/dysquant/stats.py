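"""Cohort-level inference on replicate-level values.

The Mann–Whitney U test is exact by default for small tie-free samples: the
null distribution of U is built by the standard counting recurrence
f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u) with exact integer arithmetic, and
the two-sided p is twice the smaller tail probability, capped at 1.  With
ties or larger samples the test falls back to a midrank normal approximation
with tie correction, and says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

EXACT_LIMIT = 30  # max n1 + n2 for the exact null distribution


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    n1: int
    n2: int
    u1: float  # U statistic of the first sample
    u2: float
    p: float
    method: str  # "exact" | "normal-approximation"
    has_ties: bool

    @property
    def u(self) -> float:
        return min(self.u1, self.u2)


@dataclass
class CorrelationResult:
    r: float
    n: int


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of orderings giving each U value for sample sizes m, n.

    Returns counts for U = 0 .. m*n; they sum to C(m+n, m).
    """
    if m == 0 or n == 0:
        return (1,)
    prev = _u_counts(m - 1, n)  # contributes f(m-1, n, u - n)
    counts = [0] * (m * n + 1)
    dp = list(_u_counts(m, n - 1)) + [0] * m  # length m*(n-1)+1 + m = m*n+1
    for u in range(m * n + 1):
        add = prev[u - n] if u >= n and (u - n) <= (m - 1) * n else 0
        counts[u] = dp[u] + add
    return tuple(counts)


def exact_mann_whitney(xs, ys, exact_limit: int = EXACT_LIMIT) -> GroupComparison:
    """Two-sided Mann–Whitney U test on two samples.

    U1 counts pairs (x, y) with x > y (ties count 1/2).  For tie-free samples
    with n1 + n2 <= ``exact_limit`` the exact two-sided p is
    2 * P(U <= min(U1, U2)) under the permutation null, capped at 1;
    otherwise a tie-corrected normal approximation on midranks is used and
    flagged.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = xs.size, ys.size
    diff = xs[:, None] - ys[None, :]
    u1 = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    u2 = n1 * n2 - u1
    pooled = np.concatenate([xs, ys])
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= exact_limit:
        counts = _u_counts(n1, n2)
        u_min = int(round(min(u1, u2)))
        cum = sum(counts[: u_min + 1])
        p = min(1.0, 2.0 * cum / comb(n1 + n2, n1))
        return GroupComparison(n1, n2, u1, u2, p, "exact", False)

    if has_ties and n1 + n2 <= exact_limit:
        warnings.warn(
            "ties present: falling back to tie-corrected normal approximation",
            UserWarning,
            stacklevel=2,
        )
    # midrank normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return GroupComparison(n1, n2, u1, u2, 1.0, "normal-approximation", has_ties)
    mu = n1 * n2 / 2.0
    z = (abs(u1 - mu) - 0.5) / sqrt(sigma2)  # continuity correction
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return GroupComparison(n1, n2, u1, u2, p, "normal-approximation", has_ties)


def group_summary(subjects, metric: str) -> pd.DataFrame:
    """Unweighted mean ± sample SD of a subject-level metric per phenotype.

    ``subjects`` is an iterable of objects with ``phenotype`` and the metric
    attribute, or a DataFrame with ``phenotype`` and metric columns.
    Single-subject groups report SD = 0 with ``sd_undefined`` flagged.
    """
    if isinstance(subjects, pd.DataFrame):
        df = subjects
        if metric not in df.columns:
            raise StatsError(f"unknown metric {metric!r}")
    else:
        subjects = list(subjects)
        if subjects and not hasattr(subjects[0], metric):
            raise StatsError(f"unknown metric {metric!r}")
        df = pd.DataFrame(
            {
                "phenotype": [s.phenotype for s in subjects],
                metric: [getattr(s, metric) for s in subjects],
            }
        )
    rows = []
    for group, sub in df.groupby("phenotype", sort=False):
        vals = sub[metric].to_numpy(dtype=float)
        rows.append(
            {
                "phenotype": group,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "sd_undefined": vals.size < 2,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> CorrelationResult:
    """Standard Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise StatsError("pairs must be complete (no missing values)")
    if np.var(x) == 0 or np.var(y) == 0:
        raise StatsError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=int(x.size))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (offered as an option, off by default in
    pipelines — pairwise comparisons are reported unadjusted)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
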