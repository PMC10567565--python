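"""Rank tests and multiple-testing adjustments used across modules.

The Mann-Whitney U test is computed exactly (full enumeration of group
assignments, valid under ties) whenever the enumeration is small enough, and
by the tie-corrected normal approximation with continuity correction
otherwise. Holm (step-down) and Benjamini-Hochberg (step-up) adjustments are
implemented from their defining formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

_EXACT_ENUM_CAP = 200_000


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact" or "asymptotic"
    n1: int
    n2: int


def _rank_sum_u(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2)


def mann_whitney(
    x, y, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann-Whitney U test of sample ``x`` against sample ``y``.

    ``alternative="greater"`` tests whether values of ``x`` tend to exceed
    those of ``y``. Exact enumeration (tie-safe) is used when
    C(n1+n2, min(n1, n2)) <= 200,000; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _rank_sum_u(ranks[:n1], n1)

    if comb(n1 + n2, min(n1, n2)) <= _EXACT_ENUM_CAP:
        dist = np.array(
            [
                _rank_sum_u(ranks[list(idx)], n1)
                for idx in combinations(range(n1 + n2), n1)
            ]
        )
        total = len(dist)
        p_greater = np.count_nonzero(dist >= u_obs - 1e-9) / total
        p_less = np.count_nonzero(dist <= u_obs + 1e-9) / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2 * min(p_greater, p_less))
        return MannWhitneyResult(u_obs, float(p), "exact", n1, n2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every pooled value identical
        return MannWhitneyResult(u_obs, 1.0, "asymptotic", n1, n2)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sd
        p = 2 * sps.norm.sf(z)
    return MannWhitneyResult(u_obs, float(min(1.0, p)), "asymptotic", n1, n2)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down (Bonferroni-Holm) adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m / (rank + 1) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
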