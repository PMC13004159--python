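"""Independent brute-force oracles used by the statistical tests."""

from math import comb

import numpy as np


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) by integer enumeration of the hypergeometric pmf."""
    denom = comb(N, n)
    hi = min(K, n)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), hi + 1))
    return total / denom


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q
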