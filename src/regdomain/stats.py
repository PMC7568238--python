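"""Hypergeometric upper-tail machinery and the enrichment result container.

The enrichment question everywhere in this package is the same urn problem:
a universe of N genes (or regions) contains K marked ones; a capture step
selects n of the N; k of the selected are marked.  Under the null that the
capture is blind to marking, X ~ Hypergeometric(N, K, n) and the enrichment
p-value is the upper tail P(X >= k) — the only direction consistent with
testing *enrichment*.

Tail sums are evaluated in log space (gammaln + logsumexp) so that extremely
significant results report a finite -log10 p instead of underflowing to zero;
p itself is floored at the smallest positive double on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "hypergeom_upper_tail",
    "hypergeom_log10_upper_tail",
    "hypergeom_logsf_all",
    "EnrichmentResult",
]


def _check_args(N: int, K: int, n: int, k: int) -> None:
    for label, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value:
            raise ValueError(f"{label} must be an integer, got {value!r}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")


def _log_pmf_range(N: int, K: int, n: int, j: np.ndarray) -> np.ndarray:
    """log P(X = j) for X ~ Hypergeometric(N, K, n), vectorised over j."""
    return (
        gammaln(K + 1)
        - gammaln(j + 1)
        - gammaln(K - j + 1)
        + gammaln(N - K + 1)
        - gammaln(n - j + 1)
        - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def _logsf(N: int, K: int, n: int, k: int) -> float:
    """log P(X >= k); exact 0.0 when k is at or below the lower support bound."""
    lo_support = max(0, n - (N - K))
    if k <= lo_support:
        return 0.0
    hi = min(K, n)
    j = np.arange(k, hi + 1, dtype=np.float64)
    return float(logsumexp(_log_pmf_range(N, K, n, j)))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    P(X >= 0) is exactly 1.  Probabilities below the double-precision floor
    are reported as the smallest positive normal double; use
    :func:`hypergeom_log10_upper_tail` when the magnitude matters.
    """
    _check_args(N, K, n, k)
    logp = _logsf(N, K, n, k)
    if logp == 0.0:
        return 1.0
    return max(math.exp(logp), 2.2250738585072014e-308)


def hypergeom_log10_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 P(X >= k), computed fully in log space (no underflow)."""
    _check_args(N, K, n, k)
    return _logsf(N, K, n, k) / math.log(10.0)


def hypergeom_logsf_all(N: int, K: int, n: int) -> np.ndarray:
    """log P(X >= k) for every k = 0 .. min(K, n), in one suffix pass.

    Shares the tail-summation arithmetic with the scalar API; used wherever a
    whole family of tail probabilities for one (N, K, n) is needed at once.
    """
    _check_args(N, K, n, 0)
    hi = min(K, n)
    j = np.arange(0, hi + 1, dtype=np.float64)
    log_pmf = _log_pmf_range(N, K, n, j)
    # suffix logsumexp: logsf[k] = logsumexp(log_pmf[k:])
    out = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    lo_support = max(0, n - (N - K))
    out[: lo_support + 1] = 0.0
    out = np.minimum(out, 0.0)
    return out


@dataclass
class EnrichmentResult:
    """One hypergeometric enrichment evaluation: counts, p-value and proportions.

    ``distance_bp`` is the window half-width for distance-based runs or the
    label ``"domain"`` for domain-bounded runs.  ``fold`` is the risk ratio
    (k/K) / (n/N), reported as NaN when n = 0 (0/0 is not fabricated into a
    number).  ``prop_cluster`` and ``prop_universe`` are the
    proportion-within-distance statistics (k/K and n/N).
    """

    distance_bp: int | str
    N: int
    K: int
    n: int
    k: int
    p_upper: float
    neg_log10_p: float
    fold: float
    prop_cluster: float
    prop_universe: float
    captured_ids: frozenset[str] = field(default_factory=frozenset)
    cluster: str = ""

    @classmethod
    def from_counts(
        cls,
        distance_bp: int | str,
        N: int,
        K: int,
        n: int,
        k: int,
        captured_ids: frozenset[str] = frozenset(),
        cluster: str = "",
    ) -> "EnrichmentResult":
        _check_args(N, K, n, k)
        if K == 0:
            raise ValueError("cluster size K must be positive for enrichment")
        p = hypergeom_upper_tail(N, K, n, k)
        log10p = hypergeom_log10_upper_tail(N, K, n, k)
        fold = float("nan") if n == 0 else (k / K) / (n / N)
        return cls(
            distance_bp=distance_bp,
            N=N,
            K=K,
            n=n,
            k=k,
            p_upper=p,
            neg_log10_p=-log10p,
            fold=fold,
            prop_cluster=k / K,
            prop_universe=n / N if N else 0.0,
            captured_ids=frozenset(captured_ids),
            cluster=cluster,
        )
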