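"""Brute-force statistical oracles, independent of the package's code paths.

Enumeration of the signed-rank and rank-sum null distributions for small n,
and a directly-coded step-up adjustment; used to validate the scipy/
statsmodels-backed implementations.
"""

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def signed_rank_exact_p(values) -> float:
    """Two-sided one-sample signed-rank p by enumerating all 2^n sign
    assignments (zeros must have been removed; ranks by absolute value)."""
    v = np.asarray(values, dtype=float)
    ranks = rankdata(np.abs(v))
    n = len(v)
    w_obs = ranks[v > 0].sum()
    dist = np.array([np.sum(r) if len(r := ranks[list(signs)]) else 0.0
                     for signs in product([False, True], repeat=n)], dtype=float)
    # p = 2 * min tail, capped at 1 (the convention of the exact test)
    lo = np.mean(dist <= w_obs)
    hi = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(lo, hi))


def rank_sum_exact_p(a, b) -> float:
    """Two-sided rank-sum p by enumerating all C(n+m, n) group labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    r_obs = ranks[:n].sum()
    u_obs = r_obs - n * (n + 1) / 2  # Mann-Whitney U of group a
    us = []
    for idx in combinations(range(len(pooled)), n):
        r = ranks[list(idx)].sum()
        us.append(r - n * (n + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def step_up_adjust(p_values) -> np.ndarray:
    """Step-up adjusted p-values: sort ascending, p_(i) * m / i, running
    minimum from the largest down, capped at 1, back to input order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        adj[order[k]] = min(running, 1.0)
    return adj
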