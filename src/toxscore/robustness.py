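"""Sensitivity suite for the exposure-response score and its enrichment.

Leave-one-gene-out score stability, tumor bootstrap of the adjusted
hazard ratio, size- and abundance-matched random-gene-set negative
controls, and subgroup Cox fits. All resampling is seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import DGETable
from .enrichment import hypergeom_right_tail
from .io_formats import ExpressionMatrix
from .pb_score import fit_score
from .survival import SurvivalData, build_design, cox_fit

logger = logging.getLogger(__name__)

__all__ = [
    "NullControlSpec",
    "leave_one_gene_out",
    "bootstrap_hr",
    "random_set_null",
    "subgroup_fits",
]


@dataclass(frozen=True)
class NullControlSpec:
    """Negative-control sampling: size-matched or abundance-matched."""

    mode: str = "size_matched"
    n_sets: int = 1000
    abundance_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("size_matched", "abundance_matched"):
            raise ValueError(f"unknown null-control mode {self.mode!r}")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.mode == "abundance_matched" and self.abundance_bins < 2:
            raise ValueError("abundance matching needs >= 2 bins")


def _adjusted_hr(matrix, clinical, genes, dge, stage_coding="ordinal"):
    model = fit_score(matrix, genes, dge)
    scores = pd.Series(model.scores_sd_units, index=model.barcodes)
    data, X, names, _ = build_design(clinical, scores, stage_coding=stage_coding)
    fit = cox_fit(data, X, names)
    return float(fit.hr[0]), fit


def leave_one_gene_out(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    score_genes,
    dge: DGETable,
    stage_coding: str = "ordinal",
) -> pd.DataFrame:
    """Per-gene deletion HRs for the adjusted composite-score model.

    For each gene the composite is refit without it (re-standardized)
    and the adjusted Cox model refit; the spread of HRs measures
    single-gene leverage.
    """
    score_genes = list(score_genes)
    if len(score_genes) < 2:
        raise ValueError("leave-one-gene-out requires a set of >= 2 genes")
    rows = []
    for g in score_genes:
        rest = [h for h in score_genes if h != g]
        hr, fit = _adjusted_hr(matrix, clinical, rest, dge, stage_coding)
        rows.append({"left_out": g, "hr": hr, "n": fit.n, "events": fit.n_events})
    return pd.DataFrame(rows)


def bootstrap_hr(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    score_genes,
    dge: DGETable,
    B: int = 1000,
    seed: int = 0,
    refit_z: bool = True,
    stage_coding: str = "ordinal",
) -> dict:
    """Percentile bootstrap CI of the adjusted score HR over tumor resamples.

    Tumors are resampled with replacement; per replicate the composite
    is refit (z-parameters re-estimated on the resample when
    ``refit_z``, the full-pipeline variant) and the adjusted Cox model
    refit. Replicates that fail to converge are counted; more than 10%
    failures is an error.
    """
    rng = np.random.default_rng(seed)
    model = fit_score(matrix, score_genes, dge)
    scores_full = pd.Series(model.scores_sd_units, index=model.barcodes)
    tumor_cols = np.asarray(matrix.tumor_columns)
    normal_cols = list(matrix.normal_columns)
    hrs = []
    failures = 0
    for _ in range(B):
        take = rng.integers(0, tumor_cols.size, size=tumor_cols.size)
        try:
            if refit_z:
                cols = list(tumor_cols[take]) + normal_cols
                sub = matrix.values[cols].copy()
                # resampled tumors need unique barcodes for the matrix invariant
                renamed = [f"TCGA-BS-{i:04d}-01" for i in range(tumor_cols.size)] + normal_cols
                sub.columns = renamed
                boot_matrix = ExpressionMatrix(values=sub)
                boot_model = fit_score(boot_matrix, score_genes, dge)
                scores = pd.Series(boot_model.scores_sd_units, index=boot_model.barcodes)
                # map resampled clinical rows onto the renamed barcodes
                clin = clinical.loc[[_short(c) for c in tumor_cols[take]]].copy()
                clin.index = [f"TCGA-BS-{i:04d}-01" for i in range(tumor_cols.size)]
            else:
                shorts = [_short(c) for c in tumor_cols[take]]
                scores = pd.Series(scores_full.loc[shorts].to_numpy(), index=[f"b{i}" for i in range(len(shorts))])
                clin = clinical.loc[shorts].copy()
                clin.index = [f"b{i}" for i in range(len(shorts))]
            data, X, names, _ = build_design(clin, scores, stage_coding=stage_coding)
            fit = cox_fit(data, X, names)
            hrs.append(float(fit.hr[0]))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.10 * B:
        raise ValueError(f"{failures}/{B} bootstrap replicates failed to converge")
    hrs = np.asarray(hrs)
    return {
        "hr_ci": (float(np.percentile(hrs, 2.5)), float(np.percentile(hrs, 97.5))),
        "hr_median": float(np.median(hrs)),
        "n_failed": failures,
        "hrs": hrs,
    }


def _short(full_barcode: str) -> str:
    from .io_formats import parse_barcode

    return parse_barcode(full_barcode).short


def random_set_null(
    universe,
    matrix: ExpressionMatrix,
    dge: DGETable,
    clinical: pd.DataFrame,
    observed_set,
    spec: NullControlSpec,
    deg_set=None,
    survival_null: bool = False,
) -> dict:
    """Null distributions from random gene sets matched to the observed set.

    Draws ``spec.n_sets`` sets of the observed size — uniformly from
    the universe, or stratified to match the observed set's
    mean-tumor-expression decile profile — and computes the enrichment
    p against the DEG set for each (and the adjusted score HR when
    ``survival_null``). Returns the null distributions and the observed
    statistics' empirical quantiles.
    """
    rng = np.random.default_rng(spec.seed)
    universe = sorted(set(universe))
    observed = sorted(set(observed_set) & set(universe))
    if not observed:
        raise ValueError("observed set has no genes in the universe")
    if len(universe) <= len(observed):
        raise ValueError("universe must be strictly larger than the observed set")
    deg_set = frozenset(deg_set) if deg_set is not None else dge.deg_set()
    uni_arr = np.asarray(universe)
    M = len(universe)
    K_obs = len(observed)
    deg_u = deg_set & set(universe)
    n = len(deg_u)
    deg_mask = np.isin(uni_arr, sorted(deg_u))

    if spec.mode == "abundance_matched":
        mean_expr = matrix.tumor_values.mean(axis=1)
        mean_expr = mean_expr.loc[list(uni_arr)]
        edges = np.quantile(mean_expr, np.linspace(0, 1, spec.abundance_bins + 1))
        edges[0] -= 1e-9
        bin_of = np.searchsorted(edges, mean_expr.to_numpy(), side="left") - 1
        bin_of = np.clip(bin_of, 0, spec.abundance_bins - 1)
        obs_mask = np.isin(uni_arr, observed)
        obs_hist = np.bincount(bin_of[obs_mask], minlength=spec.abundance_bins)
        pools = [np.where(bin_of == b)[0] for b in range(spec.abundance_bins)]
        for b, (need, pool) in enumerate(zip(obs_hist, pools)):
            if need > pool.size:
                raise ValueError(f"abundance bin {b} has {pool.size} genes but {need} required")

    def draw():
        if spec.mode == "size_matched":
            idx = rng.choice(M, size=K_obs, replace=False)
        else:
            parts = [rng.choice(pool, size=int(need), replace=False) for need, pool in zip(obs_hist, pools) if need > 0]
            idx = np.concatenate(parts)
        return idx

    null_p = np.empty(spec.n_sets)
    null_hr = np.full(spec.n_sets, np.nan)
    draw_histograms = []
    for i in range(spec.n_sets):
        idx = draw()
        if spec.mode == "abundance_matched":
            draw_histograms.append(np.bincount(bin_of[idx], minlength=spec.abundance_bins))
        k = int(deg_mask[idx].sum())
        null_p[i] = hypergeom_right_tail(M, K_obs, n, k)
        if survival_null:
            genes = list(uni_arr[idx])
            try:
                null_hr[i], _ = _adjusted_hr(matrix, clinical, genes, dge)
            except (ValueError, np.linalg.LinAlgError):
                null_hr[i] = np.nan

    obs_k = len(set(observed) & deg_u)
    obs_p = hypergeom_right_tail(M, K_obs, n, obs_k)
    out = {
        "null_enrichment_p": null_p,
        "observed_enrichment_p": obs_p,
        "enrichment_quantile": float(np.mean(null_p <= obs_p)),
    }
    if spec.mode == "abundance_matched":
        out["observed_bin_histogram"] = obs_hist
        out["draw_bin_histograms"] = np.vstack(draw_histograms)
    if survival_null:
        obs_hr, _ = _adjusted_hr(matrix, clinical, observed, dge)
        valid = null_hr[~np.isnan(null_hr)]
        out.update(
            {
                "null_hr": null_hr,
                "observed_hr": obs_hr,
                "hr_quantile": float(np.mean(valid <= obs_hr)) if valid.size else np.nan,
            }
        )
    return out


def subgroup_fits(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    score_genes,
    dge: DGETable,
) -> pd.DataFrame:
    """Stage- and sex-stratified adjusted Cox fits for the score.

    Stage strata (I–II vs III–IV) adjust for age only; sex strata
    adjust for age and ordinal stage. Strata without events are skipped
    with a warning.
    """
    model = fit_score(matrix, score_genes, dge)
    scores = pd.Series(model.scores_sd_units, index=model.barcodes)
    rows = []
    strata = {
        "stage_I-II": (clinical["stage"].isin(["I", "II"]), ["age"]),
        "stage_III-IV": (clinical["stage"].isin(["III", "IV"]), ["age"]),
        "sex_male": (clinical["sex"] == "male", ["age", "stage"]),
        "sex_female": (clinical["sex"] == "female", ["age", "stage"]),
    }
    for name, (mask, adjust) in strata.items():
        clin = clinical[mask]
        if clin.empty or clin["event"].fillna(0).sum() < 1:
            logger.warning("subgroup %s skipped: no records or no events", name)
            continue
        try:
            df = clin.join(scores.rename("predictor"), how="inner")
            needed = ["time", "event", "predictor", "age_years"] + (["stage"] if "stage" in adjust else [])
            df = df.dropna(subset=needed)
            x = df["predictor"].to_numpy(dtype=float)
            if x.std(ddof=1) == 0 or df["event"].sum() < 1:
                raise ValueError("degenerate stratum")
            cols = [(x - x.mean()) / x.std(ddof=1), df["age_years"].to_numpy(dtype=float) / 10.0]
            names = ["predictor_per_sd", "age_per_10y"]
            if "stage" in adjust:
                from .survival import STAGE_ORDINAL

                stage_num = df["stage"].map(STAGE_ORDINAL).to_numpy(dtype=float)
                if np.ptp(stage_num) > 0:
                    cols.append(stage_num)
                    names.append("stage_ordinal")
            data = SurvivalData(df["time"].to_numpy(float), df["event"].to_numpy(int))
            fit = cox_fit(data, np.column_stack(cols), names)
            rows.append(
                {
                    "stratum": name,
                    "hr": float(fit.hr[0]),
                    "ci_low": float(fit.ci_low[0]),
                    "ci_high": float(fit.ci_high[0]),
                    "p": float(fit.p[0]),
                    "n": fit.n,
                    "events": fit.n_events,
                }
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("subgroup %s skipped: %s", name, exc)
    return pd.DataFrame(rows)
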