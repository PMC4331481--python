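"""Shared statistical kernels.

Exact tail probabilities (no normal approximation, no continuity
correction), multiple-testing corrections and the shuffle Z-score used by
every permutation analysis in the package.  All enrichment tails are
inclusive upper tails, P(X >= k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ShuffleSummary",
    "binom_upper_tail",
    "hypergeom_upper_tail",
    "bh_fdr",
    "bonferroni",
    "shuffle_zscore",
    "two_set_proportion_test",
]


@dataclass(frozen=True)
class ShuffleSummary:
    """Observed count vs a permutation null.

    ``z = (n - s_bar) / s_std`` with ``s_std`` the sample standard deviation
    of the null counts.  When the null is degenerate (``s_std == 0``) ``z``
    is NaN and ``z_defined`` is False rather than reporting an infinity.
    """

    n: float
    s_bar: float
    s_std: float
    z: float
    n_shuffles: int

    @property
    def z_defined(self) -> bool:
        return math.isfinite(self.z)


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    if k == 0:
        return 1.0
    # survival function uses the regularized incomplete beta; exact tail
    return float(sps.binom.sf(k - 1, n, p))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size, K: marked in population, n: draws, k: marked drawn.
    """
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N, got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values: min(1, p * m), in input order."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)


def shuffle_zscore(observed: float, null_counts: Sequence[float]) -> ShuffleSummary:
    """Z-score of an observed count against permutation null counts."""
    s = np.asarray(null_counts, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 null replicates")
    s_bar = float(s.mean())
    s_std = float(s.std(ddof=1))
    z = (observed - s_bar) / s_std if s_std > 0 else float("nan")
    return ShuffleSummary(n=float(observed), s_bar=s_bar, s_std=s_std, z=z,
                          n_shuffles=int(s.size))


def two_set_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided binomial test of proportion k1/n1 against p0 = k2/n2.

    The second set supplies the reference proportion.  The tail follows the
    observed direction: upper if k1/n1 >= p0, else lower.  Degenerate
    references (p0 of 0 or 1) yield the exact degenerate tail.
    """
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts exceed trials")
    if n2 == 0:
        raise ValueError("reference set is empty")
    p0 = k2 / n2
    if n1 == 0:
        return 1.0
    if k1 / n1 >= p0:
        return binom_upper_tail(k1, n1, p0)
    return float(sps.binom.cdf(k1, n1, p0))
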