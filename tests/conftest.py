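"""Shared fixtures and independent Monte-Carlo oracles.

The permutation oracles here are deliberately independent of the package's
analytic test implementations: they operate on pooled mid-ranks and
resample group assignments directly.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import rankdata


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


def _perm_indices(rng: np.random.Generator, n_resamples: int, n_total: int) -> np.ndarray:
    idx = np.tile(np.arange(n_total), (n_resamples, 1))
    return rng.permuted(idx, axis=1)


def perm_ranksum_p(x, y, n_resamples=100_000, seed=0) -> float:
    """Two-sided permutation p for the rank-sum statistic (mid-ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, N = x.size, x.size + y.size
    ranks = rankdata(np.concatenate([x, y]))
    mu = n * (N + 1) / 2.0
    obs = abs(ranks[:n].sum() - mu)
    rng = np.random.default_rng(seed)
    idx = _perm_indices(rng, n_resamples, N)
    w = ranks[idx[:, :n]].sum(axis=1)
    hits = np.count_nonzero(np.abs(w - mu) >= obs - 1e-9)
    return (hits + 1) / (n_resamples + 1)


def _h_stat(ranks_2d: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Kruskal-Wallis H (no tie divisor; cancels in permutation comparison)."""
    N = ranks_2d.shape[-1]
    h = np.zeros(ranks_2d.shape[0] if ranks_2d.ndim == 2 else 1)
    start = 0
    for sz in sizes:
        rsum = ranks_2d[..., start:start + sz].sum(axis=-1)
        h = h + rsum * rsum / sz
        start += sz
    return 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)


def perm_kruskal_p(groups, n_resamples=100_000, seed=0) -> float:
    """Permutation p for the Kruskal-Wallis H statistic."""
    arrs = [np.asarray(g, float) for g in groups]
    sizes = [a.size for a in arrs]
    ranks = rankdata(np.concatenate(arrs))
    obs = _h_stat(ranks[None, :], sizes)[0]
    rng = np.random.default_rng(seed)
    idx = _perm_indices(rng, n_resamples, ranks.size)
    h = _h_stat(ranks[idx], sizes)
    hits = np.count_nonzero(h >= obs - 1e-9)
    return (hits + 1) / (n_resamples + 1)


def perm_dunn_p(groups, group_index, control_index,
                n_resamples=100_000, seed=0) -> float:
    """Permutation p for the mean-rank difference of one pair, ranks pooled
    over all groups (the statistic Dunn's z is a scaled version of)."""
    arrs = [np.asarray(g, float) for g in groups]
    sizes = [a.size for a in arrs]
    starts = np.cumsum([0] + sizes)
    ranks = rankdata(np.concatenate(arrs))

    def stat(r2d):
        gi = r2d[..., starts[group_index]:starts[group_index + 1]].mean(axis=-1)
        ci = r2d[..., starts[control_index]:starts[control_index + 1]].mean(axis=-1)
        return np.abs(gi - ci)

    obs = stat(ranks[None, :])[0]
    rng = np.random.default_rng(seed)
    idx = _perm_indices(rng, n_resamples, ranks.size)
    vals = stat(ranks[idx])
    hits = np.count_nonzero(vals >= obs - 1e-9)
    return (hits + 1) / (n_resamples + 1)
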