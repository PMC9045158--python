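"""Exact hypergeometric enrichment tests for the association of intergenic
features (stem-loops, promoters) with cluster architecture.

The population is the set of long intergenic regions between an SBP gene and
its cognate translocator gene, split by cluster type (SBP at the 5' end vs
the 3' end).  Feature hits are compared against sampling without
replacement; the reported p-value is the exact one-sided upper tail
P(X >= k), computed in log space from binomial coefficients — no normal
approximation.  The side with the higher hit percentage is the tested
(enriched) side.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class EnrichmentInput:
    n_5p_IRs: int
    n_3p_IRs: int
    k_5p_hits: int
    k_3p_hits: int
    feature: str  # "stemloop" | "promoter"

    def __post_init__(self) -> None:
        if min(self.n_5p_IRs, self.n_3p_IRs, self.k_5p_hits, self.k_3p_hits) < 0:
            raise ValueError("counts must be non-negative")
        if self.k_5p_hits > self.n_5p_IRs or self.k_3p_hits > self.n_3p_IRs:
            raise ValueError("hits cannot exceed IR counts")


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    p_value: float
    direction: str  # five_prime_enriched | three_prime_enriched | none
    pct_5p: float
    pct_3p: float


def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = population size, K = total successes, n = draws, k = observed
    successes among the draws.  Summed in log space over the upper tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError(f"inconsistent counts: k={k}")
    if k == 0:
        return 1.0  # exact: the whole support
    if k > min(K, n):
        return 0.0  # beyond the support
    if k > n:
        raise ValueError(f"inconsistent counts: k={k} with K={K}, n={n}")
    log_denom = _log_choose(N, n)
    total = 0.0
    for x in range(k, min(K, n) + 1):
        lw = _log_choose(K, x) + _log_choose(N - K, n - x)
        if lw == -math.inf:
            continue
        total += math.exp(lw - log_denom)
    return min(total, 1.0)


def enrichment_test(inp: EnrichmentInput) -> EnrichmentResult:
    """One-sided enrichment of a feature toward the side where it is more
    frequent, over the pooled IR population."""
    N = inp.n_5p_IRs + inp.n_3p_IRs
    K = inp.k_5p_hits + inp.k_3p_hits
    pct_5p = 100.0 * inp.k_5p_hits / inp.n_5p_IRs if inp.n_5p_IRs else 0.0
    pct_3p = 100.0 * inp.k_3p_hits / inp.n_3p_IRs if inp.n_3p_IRs else 0.0

    if pct_5p > pct_3p:
        direction = "five_prime_enriched"
        p = hypergeom_sf(N, K, inp.n_5p_IRs, inp.k_5p_hits)
    elif pct_3p > pct_5p:
        direction = "three_prime_enriched"
        p = hypergeom_sf(N, K, inp.n_3p_IRs, inp.k_3p_hits)
    else:
        direction = "none"
        p = hypergeom_sf(N, K, inp.n_5p_IRs, inp.k_5p_hits)
    return EnrichmentResult(
        feature=inp.feature, p_value=p, direction=direction, pct_5p=pct_5p, pct_3p=pct_3p
    )
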