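"""Rank-sum testing for the library-size doublet diagnostic.

The two-sided Wilcoxon rank-sum test is implemented in-repo (tie-corrected
normal approximation with continuity correction) so the pipeline's core path
has no statistical dependency; an exact permutation test over the same
statistic serves both as the small-sample method and as the oracle that
guards the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    method: str
    n_x: int
    n_y: int


def _ranks_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks and the tie-group sizes."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    tie_sizes = []
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(tie_sizes, dtype=float)


def rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of the (mid)ranks of ``x`` in the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks, _ = _ranks_with_ties(pooled)
    return float(ranks[: len(x)].sum())


def rank_sum_normal(x, y, continuity: bool = True) -> RankSumResult:
    """Two-sided rank-sum test, tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, ties = _ranks_with_ties(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(((ties**3 - ties).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(w, 1.0, "normal", n1, n2)
    dev = abs(w - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / sqrt(var)
    p = min(1.0, erfc(z / sqrt(2.0)))
    return RankSumResult(w, p, "normal", n1, n2)


def rank_sum_permutation(
    x,
    y,
    max_exact: int = 200_000,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> RankSumResult:
    """Two-sided permutation test of the rank-sum statistic.

    Enumerates all label assignments when their number is at most
    ``max_exact`` (the exact test); otherwise uses seeded Monte-Carlo
    resampling with the +1 correction.  The two-sided p-value counts
    permutations whose statistic deviates from the null mean at least as far
    as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, _ = _ranks_with_ties(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    dev_obs = abs(w_obs - mu) - 1e-9  # tolerate float fuzz in >= comparisons
    n_total = comb(n1 + n2, n1)
    if n_total <= max_exact:
        idx = np.fromiter(
            (i for c in combinations(range(n1 + n2), n1) for i in c),
            dtype=np.intp,
            count=n_total * n1,
        ).reshape(n_total, n1)
        w = ranks[idx].sum(axis=1)
        hits = int((np.abs(w - mu) >= dev_obs).sum())
        return RankSumResult(w_obs, hits / n_total, "exact_permutation", n1, n2)
    rng = np.random.default_rng(seed)
    hits = 0
    for block in range(0, n_resamples, 1024):
        k = min(1024, n_resamples - block)
        perm = rng.permuted(np.tile(ranks, (k, 1)), axis=1)
        w = perm[:, :n1].sum(axis=1)
        hits += int((np.abs(w - mu) >= dev_obs).sum())
    p = (hits + 1) / (n_resamples + 1)
    return RankSumResult(w_obs, min(1.0, p), "mc_permutation", n1, n2)


def rank_sum_test(
    x,
    y,
    method: str = "auto",
    small_group_max: int = 20,
    seed: int = 0,
) -> RankSumResult:
    """Dispatch: exact permutation when the smaller group is tiny, else the
    tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "normal-approx rank-sum" or method == "normal":
        return rank_sum_normal(x, y)
    if method == "exact permutation" or method == "permutation":
        return rank_sum_permutation(x, y, seed=seed)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if min(x.size, y.size) <= small_group_max:
        return rank_sum_permutation(x, y, seed=seed)
    return rank_sum_normal(x, y)
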