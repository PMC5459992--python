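"""Independent brute-force oracles used only by the tests.

Everything here is computed from first principles (exact rational
arithmetic, explicit enumeration) so the implementations under test can be
checked against an independent route.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p for [[a,b],[c,d]] by full hypergeometric enumeration.

    Exact rational arithmetic; includes every table whose conditional
    probability is <= that of the observed table.
    """
    n1, n2 = a + b, c + d
    K = a + c
    N = n1 + n2
    denom = comb(N, n1)
    pmf = {}
    for k in range(max(0, K - n2), min(K, n1) + 1):
        pmf[k] = Fraction(comb(K, k) * comb(N - K, n1 - k), denom)
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def hypergeom_upper_tail_exact(overlap: int, universe: int, n_success: int, n_draws: int) -> Fraction:
    """P[X >= overlap] by direct summation with exact rational arithmetic."""
    denom = comb(universe, n_draws)
    total = Fraction(0)
    for k in range(overlap, min(n_success, n_draws) + 1):
        total += Fraction(comb(n_success, k) * comb(universe - n_success, n_draws - k), denom)
    return total


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """BH q-values from the definition q_(i) = min_{j>=i} (m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(m * p[order[j]] / (j + 1) for j in range(i, m))
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_sum_two_sided_exact(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating all rank assignments (midranks)."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ranks = rankdata(np.concatenate([a, b]))
    na, nn = a.size, a.size + b.size
    w = ranks[:na].sum()
    le = ge = total = 0
    for idx in combinations(range(nn), na):
        s = ranks[list(idx)].sum()
        total += 1
        le += s <= w + 1e-9
        ge += s >= w - 1e-9
    return min(1.0, 2.0 * min(le, ge) / total)
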