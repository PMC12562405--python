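"""Tumor-level exposure-response scoring.

The primary score is a signed z-composite: per gene, expression is
z-standardized across tumors (mean 0, SD 1); the composite is the
average of those z-scores with signs taken from the tumor-vs-normal
log2 fold-change direction (positive for tumor-up genes), then
standardized to SD units over the fitting cohort. An ssGSEA-style
rank-weighted single-sample score over the same gene set serves as the
concordance check.

Normals never enter scoring: z-parameters are estimated on primary
tumor samples only, and a fitted model applied to new samples reuses
the stored parameters without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DGETable
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScoreModel", "fit_score", "ssgsea_score", "signed_ssgsea", "concordance"]


@dataclass
class ScoreModel:
    """Fitted signed z-composite: genes, signs, z-parameters, scores."""

    genes: list[str]
    signs: np.ndarray  # +1 / -1 per gene
    z_mean: np.ndarray  # per-gene mean over fitting tumors
    z_sd: np.ndarray  # per-gene SD over fitting tumors (> 0)
    barcodes: list[str] = field(default_factory=list)  # tumor short barcodes, fit order
    scores_raw: np.ndarray | None = None
    scores_sd_units: np.ndarray | None = None
    _raw_mean: float = 0.0
    _raw_sd: float = 1.0

    def apply(self, matrix: ExpressionMatrix, tumor_only: bool = True) -> pd.Series:
        """Score new samples with the stored z-parameters (no refit)."""
        cols = matrix.tumor_columns if tumor_only else list(matrix.values.columns)
        x = matrix.values.loc[self.genes, cols].to_numpy()
        z = (x - self.z_mean[:, None]) / self.z_sd[:, None]
        raw = (self.signs[:, None] * z).mean(axis=0)
        sd_units = (raw - self._raw_mean) / self._raw_sd
        from .io_formats import parse_barcode

        return pd.Series(sd_units, index=[parse_barcode(c).short for c in cols])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "short_barcode": self.barcodes,
                "score_raw": self.scores_raw,
                "score_sd_units": self.scores_sd_units,
            }
        )


def fit_score(matrix: ExpressionMatrix, overlap_genes, dge: DGETable) -> ScoreModel:
    """Fit the signed z-composite on the tumor samples of ``matrix``.

    Genes with zero tumor SD are excluded (warned); genes whose log2FC
    is exactly 0 are excluded (sign undefined, logged). Scores are
    standardized to SD units over the fitting tumors.
    """
    overlap_genes = [g for g in overlap_genes]
    missing = set(overlap_genes) - set(matrix.genes)
    if missing:
        raise ValueError(f"score genes absent from matrix: {sorted(missing)[:5]}")
    lfc = dge.frame.set_index("gene")["log2fc"]
    genes, signs = [], []
    for g in overlap_genes:
        s = np.sign(lfc.get(g, np.nan))
        if np.isnan(s):
            raise ValueError(f"gene {g} missing from the DGE table")
        if s == 0:
            logger.info("excluding %s from score: log2fc exactly 0, sign undefined", g)
            continue
        genes.append(g)
        signs.append(s)
    tumors = matrix.tumor_values.loc[genes]
    x = tumors.to_numpy()
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("excluding %d zero-tumor-SD genes from score: %s...", len(dropped), dropped[:3])
    genes = [g for g, k in zip(genes, keep) if k]
    signs = np.asarray(signs, dtype=float)[keep]
    if not genes:
        raise ValueError("no usable genes remain for scoring")
    x, mean, sd = x[keep], mean[keep], sd[keep]
    z = (x - mean[:, None]) / sd[:, None]
    raw = (signs[:, None] * z).mean(axis=0)
    raw_mean = raw.mean()
    raw_sd = raw.std(ddof=1)
    if raw_sd == 0:
        raise ValueError("composite score is constant across tumors")
    from .io_formats import parse_barcode

    return ScoreModel(
        genes=genes,
        signs=signs,
        z_mean=mean,
        z_sd=sd,
        barcodes=[parse_barcode(c).short for c in tumors.columns],
        scores_raw=raw,
        scores_sd_units=(raw - raw_mean) / raw_sd,
        _raw_mean=float(raw_mean),
        _raw_sd=float(raw_sd),
    )


def ssgsea_score(matrix: ExpressionMatrix, gene_set, alpha: float = 0.25, tumor_only: bool = True) -> pd.Series:
    """ssGSEA-style single-sample enrichment score per sample.

    Per sample, genes are ranked by expression (ascending; ties broken
    deterministically by gene name) and the score is the sum over ranks
    of the rank^alpha-weighted in-set ECDF minus the unweighted out-set
    ECDF. Scores are range-normalized across the cohort to [0, 1] and
    centered.
    """
    genes = np.asarray(matrix.genes)
    in_set = np.isin(genes, list(gene_set))
    if in_set.sum() == 0:
        raise ValueError("gene set has no genes in the matrix")
    if in_set.all():
        raise ValueError("gene set covers every gene: out-set ECDF undefined")
    cols = matrix.tumor_columns if tumor_only else list(matrix.values.columns)
    x = matrix.values[cols].to_numpy()
    m = len(genes)
    # deterministic tie-break: within equal expression, order by gene name
    name_rank = np.argsort(np.argsort(genes))
    rank_values = np.arange(m, 0, -1, dtype=float)  # rank m for the top gene
    scores = np.empty(len(cols))
    for j in range(len(cols)):
        asc = np.lexsort((name_rank, x[:, j]))
        desc = asc[::-1]  # genes from highest to lowest expression
        in_walk = in_set[desc]
        w = np.where(in_walk, rank_values**alpha, 0.0)
        ecdf_in = np.cumsum(w) / w.sum()
        ecdf_out = np.cumsum(~in_walk) / float((~in_set).sum())
        scores[j] = float(np.sum(ecdf_in - ecdf_out))
    rng_span = scores.max() - scores.min()
    if rng_span > 0:
        scores = (scores - scores.min()) / rng_span
    scores = scores - scores.mean()
    from .io_formats import parse_barcode

    return pd.Series(scores, index=[parse_barcode(c).short for c in cols])


def signed_ssgsea(matrix: ExpressionMatrix, up_genes, down_genes, alpha: float = 0.25) -> pd.Series:
    """Directional ssGSEA: score(up set) − score(down set).

    Either side may be empty (the other side alone is returned), which
    covers gene sets with a single fold-change direction.
    """
    up = [g for g in up_genes if g in set(matrix.genes)]
    down = [g for g in down_genes if g in set(matrix.genes)]
    if not up and not down:
        raise ValueError("both directional sets are empty")
    if up and down:
        return ssgsea_score(matrix, up, alpha) - ssgsea_score(matrix, down, alpha)
    if up:
        return ssgsea_score(matrix, up, alpha)
    return -ssgsea_score(matrix, down, alpha)


def concordance(a, b) -> float:
    """Sample Pearson correlation between two score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("score vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant score vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
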