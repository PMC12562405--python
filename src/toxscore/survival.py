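"""Survival machinery: Kaplan–Meier, log-rank, Cox PH with Breslow ties.

Everything here is implemented directly on the estimating equations so
that the partial likelihood, score and information are available for
oracle-level verification. The Cox fitter maximizes the Breslow partial
likelihood by Newton–Raphson with step-halving; hazard ratios for
standardized predictors are reported per 1 SD. Auxiliary procedures:
median/tertile splits, a cross-validated maximally-selected log-rank
cutpoint, a restricted-cubic-spline linearity test, and Schoenfeld-type
proportional-hazards diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal critical value

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "breslow_loglik",
    "cox_fit",
    "split_groups",
    "maxstat_cutpoint",
    "rcs_basis",
    "rcs_lr_test",
    "ph_diagnostics",
    "build_design",
]


@dataclass
class SurvivalData:
    """Aligned survival vectors: time (> 0), event indicator (0/1)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # product-limit estimate at each event time

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Breslow-tie Cox fit: per-covariate Wald inference + model stats."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    cov: np.ndarray = field(default=None, repr=False)
    n_iter: int = 0
    ties_method: str = "breslow"

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.beta + Z_95 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def km_estimate(data: SurvivalData) -> KMCurve:
    """Product-limit estimator; censored times do not drop the curve."""
    if data.n == 0:
        raise ValueError("no records")
    order = np.argsort(data.time, kind="stable")
    t, e = data.time[order], data.event[order]
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times])
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times])
    surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.array([])
    return KMCurve(times=event_times, at_risk=at_risk, n_events=d, survival=surv)


def logrank_test(a: SurvivalData, b: SurvivalData) -> LogRankResult:
    """Two-group log-rank test (O−E over pooled event times, 1 df)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both groups must be non-empty")
    if a.n_events + b.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    group = np.concatenate([np.zeros(a.n), np.ones(b.n)])
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = time >= u
        n_total = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d_total = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & (group == 0)).sum()
        e1 = d_total * n1 / n_total
        o_minus_e += d1 - e1
        if n_total > 1:
            var += d_total * (n1 / n_total) * (1 - n1 / n_total) * (n_total - d_total) / (n_total - 1)
    if var == 0:
        return LogRankResult(statistic=0.0, df=1, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(statistic=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)))


def _risk_order(data: SurvivalData):
    """Sort ascending by time; return order plus tie-block bookkeeping."""
    order = np.argsort(data.time, kind="stable")
    return order


def breslow_loglik(beta, time, event, X) -> float:
    """Breslow log partial likelihood at ``beta`` (direct evaluation)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ beta
    ll = 0.0
    for u in np.unique(np.asarray(time)[np.asarray(event) == 1]):
        at_risk = np.asarray(time) >= u
        dead = (np.asarray(time) == u) & (np.asarray(event) == 1)
        d = dead.sum()
        ll += eta[dead].sum() - d * np.log(np.exp(eta[at_risk]).sum())
    return float(ll)


def cox_fit(
    data: SurvivalData,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-9,
    ll_tol: float = 1e-12,
) -> CoxFit:
    """Newton–Raphson maximization of the Breslow partial likelihood.

    Convergence when max|score| < ``score_tol`` or the relative change
    in log partial likelihood < ``ll_tol``. Step-halving guards each
    Newton step. Errors on constant covariates, non-convergence, and
    monotone likelihood (runaway coefficients, perfect separation).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != data.n:
        X = X.T
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    if data.n_events == 0:
        raise ValueError("no events: Cox model cannot be fit")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate {names[j]!r}")

    order = np.argsort(-data.time, kind="stable")  # descending time
    t_sorted = data.time[order]
    e_sorted = data.event[order]
    X_sorted = X[order]

    # Tie blocks: indices of first occurrence of each distinct time in the
    # descending sort. The risk set at time u = all rows with time >= u =
    # prefix of the descending sort up to the end of u's tie block.
    def _eval(beta):
        eta = X_sorted @ beta
        eta_max = eta.max()
        w = np.exp(eta - eta_max)  # stabilized
        cum_w = np.cumsum(w)
        cum_wx = np.cumsum(w[:, None] * X_sorted, axis=0)
        cum_wxx = np.cumsum(w[:, None, None] * (X_sorted[:, :, None] * X_sorted[:, None, :]), axis=0)
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
                j += 1
            # block [i, j] shares one time; risk set = rows 0..j
            dead = e_sorted[i : j + 1] == 1
            d = int(dead.sum())
            if d:
                S0 = cum_w[j]
                S1 = cum_wx[j]
                S2 = cum_wxx[j]
                xbar = S1 / S0
                ll += eta[i : j + 1][dead].sum() - d * (np.log(S0) + eta_max)
                score += X_sorted[i : j + 1][dead].sum(axis=0) - d * xbar
                info += d * (S2 / S0 - np.outer(xbar, xbar))
            i = j + 1
        return ll, score, info

    beta = np.zeros(p)
    ll, score, info = _eval(beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear covariates?)") from exc
        # step-halving
        new_beta = beta + step
        new_ll, new_score, new_info = _eval(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = _eval(new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(1.0, abs(ll))
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < score_tol or rel_change < ll_tol:
            converged = True
            break
    if not converged:
        raise ValueError(f"Cox fit did not converge in {max_iter} iterations")
    # scale-aware divergence check: |beta|*sd(x) ~ spread of the linear
    # predictor; values this large mean a monotone partial likelihood
    x_sd = X.std(axis=0, ddof=1)
    if np.max(np.abs(beta) * x_sd) > 15:
        raise ValueError("monotone likelihood: coefficient diverging (perfect separation?)")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n=n,
        n_events=data.n_events,
        cov=cov,
        n_iter=it,
    )


def split_groups(values, method: str = "median") -> np.ndarray:
    """Stratum labels: median ("low"/"high", ties to low) or tertile."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("all values identical: cannot split")
    if method == "median":
        med = np.median(values)
        return np.where(values > med, "high", "low")
    if method == "tertile":
        q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
        return np.where(values > q2, "high", np.where(values > q1, "mid", "low"))
    raise ValueError(f"unknown split method {method!r}")


def maxstat_cutpoint(
    values,
    data: SurvivalData,
    folds: int = 10,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    seed: int | np.random.Generator = 0,
) -> dict:
    """Maximally-selected log-rank cutpoint with internal cross-validation.

    Candidate cuts are the distinct values within the quantile range.
    Each training fold picks the cut maximizing the log-rank statistic;
    the reported cutpoint is the median of the fold-optimal cuts, with
    held-out log-rank p per fold for honesty about the selection.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} records for {folds}-fold CV")
    lo, hi = np.quantile(values, quantile_range)
    candidates = np.unique(values[(values >= lo) & (values <= hi)])
    if candidates.size == 0:
        raise ValueError("no candidate cutpoints within the quantile range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.permutation(n)
    fold_ids = np.array_split(idx, folds)

    def best_cut(mask):
        best, best_stat = None, -1.0
        for c in candidates:
            hi_mask = values > c
            g1 = mask & hi_mask
            g0 = mask & ~hi_mask
            if g1.sum() < 2 or g0.sum() < 2:
                continue
            try:
                res = logrank_test(
                    SurvivalData(data.time[g0], data.event[g0]),
                    SurvivalData(data.time[g1], data.event[g1]),
                )
            except ValueError:
                continue
            if res.statistic > best_stat:
                best, best_stat = c, res.statistic
        return best

    fold_cuts, heldout_p = [], []
    for held in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        cut = best_cut(mask)
        if cut is None:
            continue
        fold_cuts.append(cut)
        test_mask = ~mask
        g1 = test_mask & (values > cut)
        g0 = test_mask & ~(values > cut)
        if g1.sum() >= 1 and g0.sum() >= 1 and (data.event[test_mask].sum() >= 1):
            try:
                res = logrank_test(
                    SurvivalData(data.time[g0], data.event[g0]),
                    SurvivalData(data.time[g1], data.event[g1]),
                )
                heldout_p.append(res.p)
            except ValueError:
                pass
    if not fold_cuts:
        raise ValueError("no fold produced a valid cutpoint")
    return {
        "cutpoint": float(np.median(fold_cuts)),
        "fold_cuts": [float(c) for c in fold_cuts],
        "heldout_p": [float(p) for p in heldout_p],
    }


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond the knots.

    For knots t_1 < ... < t_k, returns columns [x, s_1, ..., s_{k-2}]
    with the standard truncated-power construction that enforces
    linearity outside [t_1, t_k].
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.unique(knots).size != k:
        raise ValueError("degenerate (coincident) knots")

    def tp(v):  # truncated cube
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    t = knots
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        s = (
            tp(x - t[j])
            - tp(x - t[-2]) * (t[-1] - t[j]) / denom
            + tp(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        cols.append(s)
    return np.column_stack(cols)


def rcs_lr_test(
    data: SurvivalData,
    predictor,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    knot_quantiles: tuple[float, ...] = (0.10, 0.50, 0.90),
) -> dict:
    """Likelihood-ratio test of log-hazard linearity via a 3-knot RCS.

    Fits linear-vs-spline nested Cox models (identical adjustment set)
    and returns the LR statistic with df = knots − 2, plus the adjusted
    log-HR curve over a predictor grid.
    """
    predictor = np.asarray(predictor, dtype=float)
    knots = np.quantile(predictor, knot_quantiles)
    if np.unique(knots).size != len(knot_quantiles):
        raise ValueError("degenerate knots: coincident predictor quantiles")
    basis = rcs_basis(predictor, knots)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != data.n:
            covariates = covariates.T
        X_lin = np.column_stack([predictor, covariates])
        X_spl = np.column_stack([basis, covariates])
    else:
        X_lin = predictor[:, None]
        X_spl = basis
    fit_lin = cox_fit(data, X_lin)
    fit_spl = cox_fit(data, X_spl)
    lr = 2.0 * (fit_spl.loglik - fit_lin.loglik)
    lr = max(lr, 0.0)
    df = basis.shape[1] - 1
    grid = np.linspace(predictor.min(), predictor.max(), 100)
    grid_basis = rcs_basis(grid, knots)
    spline_beta = fit_spl.beta[: basis.shape[1]]
    log_hr_curve = grid_basis @ spline_beta
    log_hr_curve -= np.interp(np.median(predictor), grid, log_hr_curve)
    return {
        "lr_statistic": float(lr),
        "df": int(df),
        "p": float(stats.chi2.sf(lr, df)),
        "knots": [float(k) for k in knots],
        "grid": grid,
        "log_hr_curve": log_hr_curve,
        "fit_linear": fit_lin,
        "fit_spline": fit_spl,
    }


def ph_diagnostics(fit: CoxFit, data: SurvivalData, X: np.ndarray) -> pd.DataFrame:
    """Schoenfeld-type proportional-hazards diagnostics.

    Schoenfeld residuals (observed minus risk-set-weighted expected
    covariate) at each event time, correlated with event-time rank; a
    z-test on the correlation flags time-varying effects. Tied events
    each contribute a residual against the shared risk set.
    """
    if data.n_events < 2:
        raise ValueError("need at least 2 events for PH diagnostics")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != data.n:
        X = X.T
    eta = X @ fit.beta
    w = np.exp(eta - eta.max())
    rows = []
    event_times = np.sort(data.time[data.event == 1])
    for u in np.unique(event_times):
        at_risk = data.time >= u
        xbar = (w[at_risk, None] * X[at_risk]).sum(axis=0) / w[at_risk].sum()
        for i in np.where((data.time == u) & (data.event == 1))[0]:
            rows.append((u, X[i] - xbar))
    times = np.array([r[0] for r in rows])
    resid = np.vstack([r[1] for r in rows])
    rank = stats.rankdata(times)
    out = []
    d = len(rows)
    for j, name in enumerate(fit.names):
        r = np.corrcoef(rank, resid[:, j])[0, 1] if np.std(resid[:, j]) > 0 else 0.0
        if abs(r) >= 1.0:
            p = 0.0
        else:
            z = r * np.sqrt(max(d - 2, 1)) / np.sqrt(1 - r**2)
            p = 2.0 * stats.norm.sf(abs(z))
        out.append({"covariate": name, "rho": float(r), "p": float(p), "n_residuals": d})
    return pd.DataFrame(out)


STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def build_design(
    clinical: pd.DataFrame,
    predictor: pd.Series,
    stage_coding: str = "ordinal",
    adjusted: bool = True,
) -> tuple[SurvivalData, np.ndarray, list[str], pd.Index]:
    """Assemble a complete-case Cox design for one endpoint.

    ``clinical`` must carry columns time, event, age_years, sex, stage;
    ``predictor`` is indexed by short barcode and standardized to SD 1
    over the analysis set. Stage is coded ordinal 1–4 or as indicator
    variables with Stage I reference. Returns the survival data, design
    matrix, covariate names and the retained barcode index.
    """
    df = clinical.copy()
    df = df.join(predictor.rename("predictor"), how="inner")
    needed = ["time", "event", "predictor"]
    if adjusted:
        needed += ["age_years", "sex", "stage"]
    df = df.dropna(subset=needed)
    if df.empty:
        raise ValueError("no complete cases")
    x = df["predictor"].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor")
    cols = [(x - x.mean()) / sd]
    names = ["predictor_per_sd"]
    if adjusted:
        cols.append(df["age_years"].to_numpy(dtype=float) / 10.0)
        names.append("age_per_10y")
        cols.append((df["sex"] == "male").to_numpy(dtype=float))
        names.append("sex_male")
        if stage_coding == "ordinal":
            cols.append(df["stage"].map(STAGE_ORDINAL).to_numpy(dtype=float))
            names.append("stage_ordinal")
        elif stage_coding == "categorical":
            # reference = lowest stage present; indicators sum < 1 so the
            # design carries no likelihood-invariant direction
            present = [s for s in ("I", "II", "III", "IV") if (df["stage"] == s).any()]
            for s in present[1:]:
                cols.append((df["stage"] == s).to_numpy(dtype=float))
                names.append(f"stage_{s}")
        else:
            raise ValueError(f"unknown stage coding {stage_coding!r}")
    X = np.column_stack(cols)
    data = SurvivalData(df["time"].to_numpy(dtype=float), df["event"].to_numpy(dtype=int))
    return data, X, names, df.index
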