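"""Exact hypergeometric upper-tail probability.

Every significance computation in the package — feature enrichment during
model training, per-fold cross-validation significance, Fisher one-sided
over-representation, and the GWAS by-chance test — reduces to the same exact
tail: the probability of drawing at least ``k`` successes in ``n`` draws
without replacement from a population of ``N`` items containing ``K``
successes.
"""

from __future__ import annotations

from scipy.stats import hypergeom

__all__ = ["hypergeom_tail"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters
    ----------
    k : observed successes (0 <= k <= min(K, n))
    K : successes in the population
    n : number of draws
    N : population size

    Returns 1.0 for k = 0 (the whole support) and raises ``ValueError`` on
    inconsistent counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k), exact in scipy for integer support
    return float(hypergeom.sf(k - 1, N, K, n))
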