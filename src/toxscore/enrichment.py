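"""Exact hypergeometric over-representation of an exposure gene set among DEGs.

The sufficient statistics are the tuple (M, K, n, k): universe size,
exposure-set genes within the universe, DEG-set size, and overlap size.
The right tail P(X >= k) under Hypergeometric(M, K, n) is summed exactly
in log-space (log-gamma binomial coefficients); no normal or saddlepoint
approximation is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import ExpressionMatrix

__all__ = [
    "BackgroundSpec",
    "EnrichmentTuple",
    "build_universe",
    "hypergeom_right_tail",
    "enrich_overlap",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Choice of background universe for enrichment testing.

    mode:
        ``all_measured``           all retained (post-QC) genes;
        ``protein_coding``         intersection with ``coding_list``;
        ``expressed_ge_fraction``  genes above the expression floor in
                                   at least ``fraction`` of tumors.
    The floor defaults to the matrix's global minimum (a proxy for
    "non-zero expression" on log-transformed data).
    """

    mode: str = "all_measured"
    fraction: float = 0.80
    coding_list: frozenset[str] | None = None
    floor: float | None = None

    def __post_init__(self):
        if self.mode not in ("all_measured", "protein_coding", "expressed_ge_fraction"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.mode == "protein_coding" and self.coding_list is None:
            raise ValueError("protein_coding mode requires coding_list")


@dataclass(frozen=True)
class EnrichmentTuple:
    """(M, K, n, k) and the right-tail hypergeometric p-value."""

    M: int
    K: int
    n: int
    k: int
    p: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) <= self.M):
            raise ValueError(f"inconsistent enrichment tuple {self}")


def build_universe(matrix: ExpressionMatrix, spec: BackgroundSpec) -> frozenset[str]:
    """Background gene universe under the declared specification."""
    genes = frozenset(matrix.genes)
    if spec.mode == "all_measured":
        universe = genes
    elif spec.mode == "protein_coding":
        universe = genes & spec.coding_list
    else:  # expressed_ge_fraction
        tumors = matrix.tumor_values
        floor = spec.floor if spec.floor is not None else float(matrix.values.to_numpy().min())
        frac_expressed = (tumors.to_numpy() > floor).mean(axis=1)
        universe = frozenset(np.asarray(matrix.genes)[frac_expressed >= spec.fraction])
    if not universe:
        raise ValueError("background universe is empty under the given specification")
    return universe


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_right_tail(M: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k), X ~ Hypergeometric(M, K, n), in log-space.

    p = sum_{j=k}^{min(n,K)} C(K,j) C(M-K, n-j) / C(M, n), each term
    evaluated through log-gamma and combined with logsumexp so the
    result is accurate down to the smallest normal doubles.
    """
    for name, v in (("M", M), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    M, K, n, k = int(M), int(K), int(n), int(k)
    if K > M or n > M:
        raise ValueError(f"require K <= M and n <= M, got M={M}, K={K}, n={n}")
    hi = min(n, K)
    if k > hi:
        raise ValueError(f"k={k} exceeds min(n, K)={hi}")
    if k == 0:
        return 1.0
    # support lower bound: j >= max(0, n - (M - K))
    lo = max(k, n - (M - K))
    if lo > hi:
        return 0.0
    j = np.arange(lo, hi + 1)
    log_terms = _log_binom(K, j) + _log_binom(M - K, n - j) - _log_binom(M, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_overlap(
    exposure: frozenset[str] | set[str],
    degs: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    dge_frame=None,
) -> tuple[EnrichmentTuple, list[str]]:
    """Intersect the exposure set with the DEG set inside the universe.

    Both sets are clipped to the universe before counting; genes outside
    the universe never contribute to K, n or k. K = 0 or n = 0 is an
    error (the test is uninterpretable), distinct from k = 0 (valid,
    p = 1). The overlap gene list is sorted by the DGE table's (q,
    |log2fc|) when ``dge_frame`` is given, else lexicographically.
    """
    universe = frozenset(universe)
    exp_u = frozenset(exposure) & universe
    deg_u = frozenset(degs) & universe
    M, K, n = len(universe), len(exp_u), len(deg_u)
    if K == 0:
        raise ValueError("exposure set has no genes in the universe (K=0): test uninterpretable")
    if n == 0:
        raise ValueError("DEG set has no genes in the universe (n=0): test uninterpretable")
    overlap = exp_u & deg_u
    k = len(overlap)
    p = hypergeom_right_tail(M, K, n, k)
    if dge_frame is not None:
        ranked = dge_frame[dge_frame["gene"].isin(overlap)]
        overlap_list = list(ranked["gene"])  # dge frame already sorted by q then |lfc|
    else:
        overlap_list = sorted(overlap)
    return EnrichmentTuple(M=M, K=K, n=n, k=k, p=p), overlap_list
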