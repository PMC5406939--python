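"""Shared exact-test machinery.

The per-cytosine callers run two-sided Fisher's exact tests over 10^4-10^6
2x2 tables at a time, so the test is evaluated in vectorized form from the
hypergeometric pmf rather than by looping over ``scipy.stats.fisher_exact``
(which remains the independent oracle in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

# relative tolerance when comparing pmf values to the observed table's pmf,
# matching the convention of scipy's two-sided Fisher test
_REL_TOL = 1.0 + 1e-7


def fisher_exact_two_sided(m1, u1, m2, u2) -> np.ndarray:
    """Two-sided Fisher's exact p for arrays of 2x2 tables.

    Each table is ``[[m1, u1], [m2, u2]]`` (methylated / unmethylated read
    counts in two samples). The two-sided p value is the total probability,
    under the hypergeometric null with the table's margins fixed, of all
    tables at most as probable as the observed one.
    """
    m1 = np.asarray(m1, dtype=np.int64)
    u1 = np.asarray(u1, dtype=np.int64)
    m2 = np.asarray(m2, dtype=np.int64)
    u2 = np.asarray(u2, dtype=np.int64)
    if m1.ndim == 0:
        return float(fisher_exact_two_sided([m1], [u1], [m2], [u2])[0])

    total = m1 + u1 + m2 + u2
    successes = m1 + m2          # margin: methylated reads overall
    draws = m1 + u1              # margin: reads in sample 1
    lo = np.maximum(0, draws - (total - successes))
    hi = np.minimum(draws, successes)

    width = int((hi - lo).max()) + 1 if len(m1) else 1
    support = lo[:, None] + np.arange(width)[None, :]
    valid = support <= hi[:, None]
    pmf = hypergeom.pmf(np.where(valid, support, lo[:, None]),
                        total[:, None], successes[:, None], draws[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = hypergeom.pmf(m1, total, successes, draws)
    p = np.where(pmf <= obs[:, None] * _REL_TOL, pmf, 0.0).sum(axis=1)
    p = np.where(total == 0, 1.0, p)  # empty table carries no evidence
    return np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (empty-safe)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def hypergeom_upper_tail(k: int, universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, n_a, n_b).

    Upper-tail probability of observing an overlap of at least ``k`` between
    a set of size ``n_a`` and a set of size ``n_b`` drawn from ``universe``.
    """
    return float(hypergeom.sf(k - 1, universe, n_a, n_b))
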