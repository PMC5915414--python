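"""Independent brute-force oracles shared by the test modules.

Each function here recomputes a quantity by exhaustive enumeration or a
direct set formula, deliberately avoiding the code paths it is used to
check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def enumerate_presence_probability(coverages) -> float:
    """P(present in >= 1 covered cell) by summing over all 2^n independent
    presence/absence configurations of the occupied cells."""
    c = np.asarray(coverages, dtype=float)
    n = c.size
    if n == 0:
        return 0.0
    bits = np.array(list(itertools.product([0, 1], repeat=n)), dtype=bool)
    config_p = np.where(bits, c, 1.0 - c).prod(axis=1)
    return float(config_p[bits.any(axis=1)].sum())


def signed_rank_p_enumeration(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([False, True], repeat=n):
        stats.append(ranks[list(signs)].sum())
    stats = np.asarray(stats)
    lo = (stats <= observed + 1e-9).mean()
    hi = (stats >= observed - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def rank_sum_p_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = x.size
    u_obs = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    stats = []
    for comb in itertools.combinations(range(pooled.size), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        stats.append(
            (xs[:, None] > ys[None, :]).sum() + 0.5 * (xs[:, None] == ys[None, :]).sum()
        )
    stats = np.asarray(stats, dtype=float)
    lo = (stats <= u_obs + 1e-9).mean()
    hi = (stats >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def sorensen_simpson(x_set: set, y_set: set) -> tuple[float, float]:
    """Set-based Sorensen and Simpson dissimilarities for binary data."""
    a = len(x_set & y_set)
    b = len(x_set - y_set)
    c = len(y_set - x_set)
    sorensen = (b + c) / (2 * a + b + c)
    simpson = min(b, c) / (a + min(b, c)) if (a + min(b, c)) else 0.0
    return sorensen, simpson
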