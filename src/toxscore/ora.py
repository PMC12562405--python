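"""Pathway over-representation analysis of the exposure–DEG overlap.

Per term: K = members within the universe (terms outside the 10–500
size window are excluded before testing), hypergeometric right-tail p
against the query, and BH FDR computed separately within each
collection. GeneRatio = k/n follows the usual ORA reporting convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dge import bh_adjust
from .enrichment import hypergeom_right_tail
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ORATerm", "run_ora", "summarize_top", "collapse_redundant"]


@dataclass(frozen=True)
class ORATerm:
    collection: str
    term: str
    k: int
    n: int
    K: int
    M: int
    gene_ratio: float
    p: float
    fdr: float
    overlap_genes: tuple[str, ...]


def run_ora(
    query,
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 500,
    size_on_raw_membership: bool = False,
) -> list[ORATerm]:
    """Hypergeometric ORA of ``query`` against every term of a collection.

    The query is clipped to the universe. Term size is measured after
    intersection with the universe by default (``size_on_raw_membership``
    applies the 10–500 filter to raw membership instead). BH adjustment
    runs across the retained terms of this collection only.
    """
    universe = frozenset(universe)
    M = len(universe)
    query_u = frozenset(query) & universe
    n = len(query_u)
    if n == 0:
        raise ValueError("query set is empty after clipping to the universe")
    if len(collection) == 0:
        raise ValueError(f"collection {collection.name!r} is empty")

    rows = []
    for term, (_, members) in collection.sets.items():
        members_u = members & universe
        size = len(members) if size_on_raw_membership else len(members_u)
        if not (min_size <= size <= max_size):
            continue
        K = len(members_u)
        if K == 0:
            continue
        overlap = members_u & query_u
        k = len(overlap)
        p = hypergeom_right_tail(M, K, n, k)
        rows.append((term, k, K, p, tuple(sorted(overlap))))
    if not rows:
        logger.warning("ORA: all terms of %s filtered out by the size window", collection.name)
        return []

    fdrs = bh_adjust([r[3] for r in rows])
    results = [
        ORATerm(
            collection=collection.name,
            term=term,
            k=k,
            n=n,
            K=K,
            M=M,
            gene_ratio=k / n,
            p=p,
            fdr=float(fdr),
            overlap_genes=overlap,
        )
        for (term, k, K, p, overlap), fdr in zip(rows, fdrs)
    ]
    results.sort(key=lambda t: (t.fdr, t.p, -t.gene_ratio, t.term))
    return results


def summarize_top(results: list[ORATerm], per_collection: int = 20) -> pd.DataFrame:
    """Top terms per collection ranked by (FDR, p, GeneRatio desc)."""
    frames = []
    by_collection: dict[str, list[ORATerm]] = {}
    for t in results:
        by_collection.setdefault(t.collection, []).append(t)
    for name, terms in by_collection.items():
        terms = sorted(terms, key=lambda t: (t.fdr, t.p, -t.gene_ratio, t.term))[:per_collection]
        frames.append(
            pd.DataFrame(
                {
                    "collection": name,
                    "term": [t.term for t in terms],
                    "gene_ratio": [t.gene_ratio for t in terms],
                    "K": [t.K for t in terms],
                    "p": [t.p for t in terms],
                    "fdr": [t.fdr for t in terms],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["collection", "term", "gene_ratio", "K", "p", "fdr"])
    return pd.concat(frames, ignore_index=True)


def collapse_redundant(results: list[ORATerm], jaccard_threshold: float = 0.5) -> list[ORATerm]:
    """Greedy overlap collapse for report readability (non-canonical).

    Walks terms in rank order and drops any term whose overlap-gene set
    has Jaccard similarity above the threshold with an already-retained
    term. A pragmatic stand-in for semantic-similarity consolidation;
    affects display only, never inference.
    """
    kept: list[ORATerm] = []
    for t in results:
        s = set(t.overlap_genes)
        redundant = False
        for u in kept:
            su = set(u.overlap_genes)
            union = len(s | su)
            if union and len(s & su) / union > jaccard_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(t)
    return kept
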