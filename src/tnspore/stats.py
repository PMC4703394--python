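"""Mann-Whitney U machinery for insertion-count profiles.

Tn-seq count vectors are small (one value per TA site of a gene or window)
and heavily tied (shared zeros at unoccupied sites), so the workhorse here
is an *exact, tie-aware* permutation distribution of the rank sum: midranks
are doubled to integers and a subset-sum dynamic program counts, for every
achievable rank sum, the number of size-n1 subsets of the pooled sample
attaining it.  This is exhaustive enumeration over all C(n1+n2, n1) group
assignments, computed in polynomial time, and is exact in the presence of
arbitrary ties.  For larger samples the standard normal approximation with
tie and continuity corrections (scipy) is used.

The two-sided p-value is P(|S - E[S]| >= |s_obs - E[S]|) under the
permutation null.  For equal group sizes (the only case arising here: the
two libraries are compared over the same TA sites) the null is symmetric,
so this coincides with the usual doubled one-tail definition.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["mann_whitney_exact", "mann_whitney", "MWUResult"]


def _doubled_midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks of the pooled sample, doubled so ties (x.5) become integers."""
    r2 = 2.0 * rankdata(pooled, method="average")
    out = np.rint(r2).astype(np.int64)
    if not np.allclose(r2, out):
        raise AssertionError("doubled midranks must be integral")
    return out


def _rank_sum_counts(dranks: np.ndarray, n1: int) -> np.ndarray:
    """counts[s] = number of size-``n1`` subsets of ``dranks`` with sum s.

    Subset-sum DP; with N pooled observations the table is
    (n1+1) x (sum(dranks)+1) int64 — exact for the N <= ~30 arising here.
    """
    total = int(dranks.sum())
    table = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    table[0, 0] = 1
    for r in dranks:
        r = int(r)
        # descending k so each item is used at most once
        for k in range(n1, 0, -1):
            table[k, r:] += table[k - 1, : total + 1 - r]
    return table[n1]


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by exhaustive enumeration.

    Returns ``(U, p)`` where U is the U statistic of ``x`` (ties counted
    half) and p is exact under the permutation null, tie-aware.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    dranks = _doubled_midranks(pooled)
    s_obs = int(dranks[:n1].sum())
    u1 = s_obs / 2.0 - n1 * (n1 + 1) / 2.0

    counts = _rank_sum_counts(dranks, n1)
    # sum of doubled midranks over the pool is N(N+1), so E[S_doubled] = n1(N+1)
    center = n1 * (n1 + n2 + 1)
    dev_obs = abs(s_obs - center)
    tail = np.abs(np.arange(counts.size) - center) >= dev_obs
    p = counts[tail].sum() / comb(n1 + n2, n1)
    return u1, float(p)


def _all_tied(pooled: np.ndarray) -> bool:
    return bool(np.all(pooled == pooled[0]))


class MWUResult(tuple):
    """(U, p) pair; named for readability at call sites."""
    __slots__ = ()

    @property
    def u(self):
        return self[0]

    @property
    def p(self):
        return self[1]


def mann_whitney(x, y, exact_max_n: int = 8) -> MWUResult:
    """Two-sided Mann-Whitney U comparing two per-site count vectors.

    Exact by enumeration when both samples have at most ``exact_max_n``
    observations; otherwise normal approximation with tie correction and
    continuity correction.  A fully tied pooled sample (e.g. two all-zero
    genes) carries no evidence and returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if _all_tied(pooled):
        return MWUResult((n1 * n2 / 2.0, 1.0))
    if max(n1, n2) <= exact_max_n:
        return MWUResult(mann_whitney_exact(x, y))
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return MWUResult((float(res.statistic), float(res.pvalue)))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional output column of the screen)."""
    from scipy.stats import false_discovery_control

    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = false_discovery_control(p[ok], method="bh")
    return q
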