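"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: isotonic fits are
found by exhaustive search over consecutive-block partitions, bandwidths
by dense-grid scans of the cross-validation objective, and sign-test ranks
by a direct scan of the exact binomial CDF.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import binom


def brute_force_monotone_fit(y, direction: int) -> np.ndarray:
    """Exact least-squares monotone fit by enumerating block partitions.

    Any optimal monotone fit is piecewise constant with each block at its
    mean, so scanning all 2^(n-1) partitions into consecutive blocks and
    keeping the feasible one with the smallest SSE is an exact (if
    exponential) solution.  Only usable for short rows.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    assert n <= 12, "brute force oracle is exponential"
    z = y if direction == 1 else y[::-1]
    best, best_sse = None, np.inf
    for cuts in product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [z[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        if any(m2 < m1 for m1, m2 in zip(means[:-1], means[1:])):
            continue
        fit = np.concatenate(
            [np.full(b - a, m) for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means)]
        )
        sse = float(np.sum((fit - z) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = fit, sse
    return best if direction == 1 else best[::-1]


def dense_grid_bcv(x, n_grid: int = 10_000) -> float:
    """Minimize the biased cross-validation objective on a dense grid."""
    from acmgcalib.density_engine import bcv_objective, _pairwise_sq_diffs

    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    hmax = 1.144 * sd * x.size ** (-1 / 5)
    hs = np.linspace(0.1 * hmax, hmax, n_grid)
    sq = _pairwise_sq_diffs(x)
    vals = np.array([bcv_objective(h, sq, x.size) for h in hs])
    return float(hs[int(np.argmin(vals))])


def scan_sign_test_ranks(n: int, level: float) -> tuple[int, int]:
    """Exhaustive scan of k against the exact Binomial(n, 1/2) CDF."""
    alpha = (1.0 - level) / 2.0
    lo = None
    for k in range(1, n + 1):
        if binom.cdf(k - 1, n, 0.5) <= alpha:
            lo = k
    assert lo is not None
    return lo, n + 1 - lo
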