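"""Shared statistical primitives.

The two-sided Fisher exact test implemented here is the work-horse of the
differential-methylation stage, where it is evaluated once per CpG site over
pooled read counts; it is therefore written against the hypergeometric
log-pmf with ``scipy.special.gammaln`` rather than calling
``scipy.stats.fisher_exact`` in a per-site loop.  The two-sided p-value uses
the standard "sum of outcomes no more probable than the observed table"
rule, conditioning on both margins.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

# Relative tolerance for the pmf(k) <= pmf(observed) tie comparison, applied
# on the log scale.  It absorbs floating-point rounding of genuinely equal
# probabilities (symmetric tables) without admitting distinct outcomes.
_TIE_LOG_TOL = 1e-9


def hypergeom_logpmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P[X = k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    k = np.asarray(k, dtype=np.float64)
    return (
        _logchoose(K, k)
        + _logchoose(N - K, n - k)
        - _logchoose(N, n)
    )


def _logchoose(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Conditional on both margins; the p-value sums the hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise DomainError("2x2 table cells must be non-negative")
    n1, n2 = a + b, c + d
    K = a + c
    N = n1 + n2
    if N == 0:
        raise DomainError("empty 2x2 table")
    lo, hi = max(0, K - n2), min(K, n1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom_logpmf(support, N, K, n1)
    log_obs = logpmf[a - lo]
    p = float(np.exp(logpmf[logpmf <= log_obs + _TIE_LOG_TOL]).sum())
    return min(p, 1.0)


def fisher_exact_vec(a, b, c, d) -> np.ndarray:
    """Vectorised :func:`fisher_exact_two_sided` over equal-length arrays."""
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    out = np.empty(a.shape, dtype=np.float64)
    for i in range(a.size):
        out.flat[i] = fisher_exact_two_sided(
            int(a.flat[i]), int(b.flat[i]), int(c.flat[i]), int(d.flat[i])
        )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(overlap: int, universe: int, n_success: int, n_draws: int) -> float:
    """P[X >= overlap] for X ~ Hypergeometric(universe, n_success, n_draws)."""
    if not (0 <= n_success <= universe and 0 <= n_draws <= universe):
        raise DomainError("hypergeometric parameters outside domain")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_success, n_draws))
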