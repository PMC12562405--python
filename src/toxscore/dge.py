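"""Tumor-vs-normal differential expression.

Per-gene Welch's t-test on log2 expression, Benjamini–Hochberg FDR over
the retained gene universe, DESeq2-style significance thresholds
(FDR < 0.05, optionally |log2FC| >= 1), and top-candidate selection.

log2FC convention: difference of group means of already-log2 values,
tumor minus normal, so positive values mean higher expression in tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DGERecord", "DGETable", "welch_t", "welch_t_matrix", "bh_adjust", "run_dge", "select_top"]


@dataclass(frozen=True)
class DGERecord:
    gene: str
    log2fc: float
    t_stat: float
    df: float
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05

    @property
    def strict(self) -> bool:
        return self.significant and abs(self.log2fc) >= 1.0


@dataclass
class DGETable:
    """One record per universe gene, plus the BH universe size.

    ``frame`` columns: gene, log2fc, t, df, p, q, significant, strict.
    Rows are sorted by (q, p, -|log2fc|, gene) for reproducible output.
    """

    frame: pd.DataFrame
    fdr: float = 0.05
    lfc: float = 1.0

    @property
    def m(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return list(self.frame["gene"])

    def deg_set(self, strict: bool = False) -> frozenset[str]:
        flag = "strict" if strict else "significant"
        return frozenset(self.frame.loc[self.frame[flag], "gene"])

    def record(self, gene: str) -> DGERecord:
        row = self.frame.set_index("gene").loc[gene]
        return DGERecord(gene, row["log2fc"], row["t"], row["df"], row["p"], row["q"])


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch–Satterthwaite df, two-sided p).

    t = (mean(x) - mean(y)) / sqrt(s²x/nx + s²y/ny). Degenerate case of
    both sample variances zero: p = 1 if the means agree, else a p = 0
    sentinel (with a warning) since the samples are perfectly separated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    dmean = x.mean() - y.mean()
    if vx == 0.0 and vy == 0.0:
        if dmean == 0.0:
            return 0.0, float(x.size + y.size - 2), 1.0
        logger.warning("welch_t: zero variance in both groups with unequal means; p=0 sentinel")
        return np.inf if dmean > 0 else -np.inf, float(x.size + y.size - 2), 0.0
    a = vx / x.size
    b = vy / y.size
    t = dmean / np.sqrt(a + b)
    df = (a + b) ** 2 / (a**2 / (x.size - 1) + b**2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t over gene × sample arrays (vectorized)."""
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("need >=2 samples per group")
    a = x.var(axis=1, ddof=1) / nx
    b = y.var(axis=1, ddof=1) / ny
    dmean = x.mean(axis=1) - y.mean(axis=1)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dmean / np.sqrt(denom)
        df = denom**2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    # degenerate rows: both variances zero
    degenerate = denom == 0
    t = np.where(degenerate, np.where(dmean == 0, 0.0, np.sign(dmean) * np.inf), t)
    df = np.where(degenerate, float(nx + ny - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(dmean == 0, 1.0, 0.0), p)
    return t, df, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} min(1, p(j)·m/j) over ascending-sorted p,
    returned in the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_dge(matrix: ExpressionMatrix, fdr: float = 0.05, lfc: float = 1.0) -> DGETable:
    """Per-gene tumor-vs-normal Welch t screen with BH FDR.

    The BH universe is exactly the retained (post-QC) genes of the
    matrix. Output rows are sorted by (q, p, -|log2fc|, gene).
    """
    tumors = matrix.tumor_values.to_numpy()
    normals = matrix.normal_values.to_numpy()
    if tumors.shape[1] < 2 or normals.shape[1] < 2:
        raise ValueError("run_dge requires at least 2 tumors and 2 normals")
    t, df, p = welch_t_matrix(tumors, normals)
    log2fc = tumors.mean(axis=1) - normals.mean(axis=1)
    q = bh_adjust(p)
    frame = pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
        }
    )
    frame["significant"] = frame["q"] < fdr
    frame["strict"] = frame["significant"] & (frame["log2fc"].abs() >= lfc)
    frame = frame.sort_values(
        by=["q", "p", "log2fc", "gene"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="stable",
    ).reset_index(drop=True)
    return DGETable(frame=frame, fdr=fdr, lfc=lfc)


def select_top(table: DGETable, k: int = 10) -> pd.DataFrame:
    """The k lowest-FDR genes; ties broken by larger |log2FC|, then name."""
    if table.m == 0:
        raise ValueError("empty DGE table")
    if k > table.m:
        logger.warning("select_top: k=%d exceeds table size %d; returning all", k, table.m)
        k = table.m
    return table.frame.head(k).copy()
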