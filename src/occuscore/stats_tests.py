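"""Rank-based and parametric hypothesis tests with tie handling.

All tests are two-sided. The rank-sum test switches to exact enumeration
for small tie-free samples (both n <= ``exact_threshold``, default 8),
where the normal approximation is unreliable; otherwise a tie-corrected
normal approximation with optional continuity correction is used.

Degenerate all-tied inputs return a defined null result (statistic 0,
p = 1) rather than raising, so batch pipelines keep running; a warning
is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import f as _f
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_posthoc",
    "one_way_anova",
    "bonferroni_adjust",
    "holm_sidak_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    ties_corrected: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError(f"non-finite test statistic: {self.statistic}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_1d(name: str, x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"empty sample for {name!r}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in sample {name!r}")
    return arr


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(pooled, return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_threshold: int = 8,
    continuity: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum null distribution is used when both
    samples have at most ``exact_threshold`` observations and the pooled
    data are tie-free; otherwise the tie-corrected normal approximation is
    used (with continuity correction unless ``continuity=False``).
    """
    xa = _as_1d("x", x)
    ya = _as_1d("y", y)
    n, m = xa.size, ya.size
    N = n + m
    pooled = np.concatenate([xa, ya])
    ranks = _rankdata(pooled)
    w = float(ranks[:n].sum())
    mu = n * (N + 1) / 2.0
    tie_sum = _tie_sum(pooled)
    has_ties = tie_sum > 0

    if n <= exact_threshold and m <= exact_threshold and not has_ties:
        # Enumerate all C(N, n) assignments of ranks to the first sample.
        dev = abs(w - mu)
        hits = 0
        total = 0
        all_ranks = tuple(range(1, N + 1))
        for combo in combinations(all_ranks, n):
            total += 1
            if abs(sum(combo) - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
        return TestResult(
            statistic=w,
            p_value=min(1.0, p),
            method="wilcoxon_rank_sum_exact",
            n_per_group=(n, m),
            ties_corrected=False,
        )

    var = n * m / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
    if var <= 0:
        logger.warning("rank-sum: all pooled values tied; returning p = 1")
        return TestResult(
            statistic=w, p_value=1.0, method="wilcoxon_rank_sum_normal",
            n_per_group=(n, m), ties_corrected=True,
        )
    dev = abs(w - mu)
    if continuity:
        dev = max(0.0, dev - 0.5)
    z = dev / math.sqrt(var)
    p = float(2.0 * _norm.sf(z))
    return TestResult(
        statistic=w,
        p_value=min(1.0, p),
        method="wilcoxon_rank_sum_normal",
        n_per_group=(n, m),
        ties_corrected=has_ties,
        extra={"z": z if w >= mu else -z},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    Returns the chi-square p-value on k - 1 degrees of freedom.  If every
    pooled value is identical, the defined degenerate result H = 0, p = 1
    is returned with a logged warning.
    """
    if len(groups) < 2:
        raise ValueError(f"kruskal_wallis requires >= 2 groups, got {len(groups)}")
    arrs = [_as_1d(f"group {i}", g) for i, g in enumerate(groups)]
    sizes = [a.size for a in arrs]
    N = sum(sizes)
    if N < 3:
        raise ValueError(f"kruskal_wallis requires total n >= 3, got {N}")
    pooled = np.concatenate(arrs)
    ranks = _rankdata(pooled)
    tie_sum = _tie_sum(pooled)
    correction = 1.0 - tie_sum / (N**3 - N)
    if correction <= 0:
        logger.warning("kruskal_wallis: all values tied; returning H = 0, p = 1")
        return TestResult(
            statistic=0.0, p_value=1.0, method="kruskal_wallis",
            n_per_group=tuple(sizes), ties_corrected=True,
        )
    h = 0.0
    start = 0
    for sz in sizes:
        rsum = ranks[start:start + sz].sum()
        h += rsum * rsum / sz
        start += sz
    h = (12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)) / correction
    h = max(0.0, h)
    p = float(_chi2.sf(h, df=len(sizes) - 1))
    return TestResult(
        statistic=h,
        p_value=p,
        method="kruskal_wallis",
        n_per_group=tuple(sizes),
        ties_corrected=tie_sum > 0,
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    adjust: str = "bonferroni",
    *,
    method: str = "normal",
    small_threshold: int = 8,
    n_resamples: int = 10_000,
    perm_seed: int = 0,
) -> list[TestResult]:
    """Dunn's pairwise post-hoc comparisons of each group versus a control.

    Uses pooled mid-ranks with the tie-corrected variance
    ``N(N+1)/12 - sum(t^3 - t)/(12(N-1))`` and a two-sided normal p-value
    per pair.  ``adjust`` is ``"bonferroni"`` (p multiplied by the number of
    reported pairs, capped at 1) or ``"none"``.

    ``method`` selects how the two-sided p is obtained: ``"normal"`` (the
    classical approximation), ``"permutation"`` (Monte Carlo permutation of
    the pooled ranks, ``n_resamples`` draws, seeded by ``perm_seed`` for
    determinism), or ``"auto"`` (permutation whenever the smallest group
    has at most ``small_threshold`` observations, where the normal
    approximation is unreliable).  The z statistic is identical in all
    modes.
    """
    if len(groups) < 2:
        raise ValueError(f"dunn_posthoc requires >= 2 groups, got {len(groups)}")
    if not 0 <= control_index < len(groups):
        raise ValueError(
            f"control_index {control_index} out of range for {len(groups)} groups"
        )
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment scheme: {adjust!r}")
    if method not in ("normal", "permutation", "auto"):
        raise ValueError(f"unknown method: {method!r}")
    arrs = [_as_1d(f"group {i}", g) for i, g in enumerate(groups)]
    sizes = [a.size for a in arrs]
    N = sum(sizes)
    pooled = np.concatenate(arrs)
    ranks = _rankdata(pooled)
    tie_sum = _tie_sum(pooled)
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    starts = np.cumsum([0] + sizes)
    mean_ranks = [ranks[starts[i]:starts[i + 1]].mean() for i in range(len(sizes))]
    if method == "auto":
        method = "permutation" if min(sizes) <= small_threshold else "normal"
    perm_rng = np.random.default_rng(perm_seed) if method == "permutation" else None
    pairs = [i for i in range(len(arrs)) if i != control_index]
    m = len(pairs)
    results = []
    for i in pairs:
        if var_term <= 0:
            logger.warning("dunn_posthoc: all values tied; returning p = 1")
            z, p = 0.0, 1.0
        else:
            se = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[control_index]))
            z = (mean_ranks[i] - mean_ranks[control_index]) / se
            if method == "permutation":
                p = _perm_pair_p(ranks, starts, i, control_index,
                                 n_resamples, perm_rng)
            else:
                p = float(2.0 * _norm.sf(abs(z)))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        results.append(
            TestResult(
                statistic=z,
                p_value=min(1.0, p),
                method="dunn",
                n_per_group=(sizes[i], sizes[control_index]),
                ties_corrected=tie_sum > 0,
                extra={"p_adjusted": p_adj, "group_index": i,
                       "control_index": control_index, "n_comparisons": m},
            )
        )
    return results


def _perm_pair_p(
    ranks: np.ndarray,
    starts: np.ndarray,
    group_index: int,
    control_index: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> float:
    """Monte Carlo permutation p for one pair's mean-rank difference,
    ranks pooled over all groups (add-one estimator)."""
    obs = abs(
        ranks[starts[group_index]:starts[group_index + 1]].mean()
        - ranks[starts[control_index]:starts[control_index + 1]].mean()
    )
    idx = rng.permuted(
        np.tile(np.arange(ranks.size), (n_resamples, 1)), axis=1
    )
    perm = ranks[idx]
    diff = np.abs(
        perm[:, starts[group_index]:starts[group_index + 1]].mean(axis=1)
        - perm[:, starts[control_index]:starts[control_index + 1]].mean(axis=1)
    )
    hits = int(np.count_nonzero(diff >= obs - 1e-9))
    return (hits + 1) / (n_resamples + 1)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F test."""
    if len(groups) < 2:
        raise ValueError(f"one_way_anova requires >= 2 groups, got {len(groups)}")
    arrs = [_as_1d(f"group {i}", g) for i, g in enumerate(groups)]
    sizes = [a.size for a in arrs]
    if any(sz < 2 for sz in sizes):
        raise ValueError("one_way_anova requires n >= 2 in every group")
    k = len(arrs)
    N = sum(sizes)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(sz * (a.mean() - grand) ** 2 for a, sz in zip(arrs, sizes))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, N - k
    if ss_within <= 0:
        if ss_between <= 0:
            logger.warning("one_way_anova: zero variance everywhere; p = 1")
            return TestResult(0.0, 1.0, "one_way_anova", tuple(sizes))
        raise ValueError("one_way_anova: zero within-group variance with unequal means")
    fstat = (ss_between / df_b) / (ss_within / df_w)
    p = float(_f.sf(fstat, df_b, df_w))
    return TestResult(
        statistic=float(fstat), p_value=p, method="one_way_anova",
        n_per_group=tuple(sizes),
    )


def _check_pvals(pvals: Sequence[float]) -> np.ndarray:
    arr = np.asarray(pvals, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError(f"p-values outside [0, 1]: {arr}")
    return arr


def bonferroni_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for m tests."""
    arr = _check_pvals(pvals)
    return np.minimum(1.0, arr * arr.size)


def holm_sidak_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, the i-th smallest p (0-based) becomes
    ``1 - (1 - p)^(m - i)``, with a running maximum enforcing monotonicity.
    """
    arr = _check_pvals(pvals)
    m = arr.size
    order = np.argsort(arr, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - arr[idx]) ** (m - i)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj
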