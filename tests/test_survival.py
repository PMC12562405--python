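import numpy as np
import pytest

from toxscore.survival import (
    SurvivalData,
    breslow_loglik,
    build_design,
    cox_fit,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    ph_diagnostics,
    rcs_basis,
    rcs_lr_test,
    split_groups,
)


def brute_force_breslow(beta, time, event, X):
    """Independent oracle: direct product over risk sets (tie-free)."""
    beta = np.atleast_1d(beta)
    X = np.atleast_2d(X)
    if X.shape[0] != len(time):
        X = X.T
    ll = 0.0
    for i in np.where(np.asarray(event) == 1)[0]:
        risk = np.asarray(time) >= time[i]
        ll += float(X[i] @ beta) - np.log(np.exp(X[risk] @ beta).sum())
    return ll


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate(SurvivalData([1, 2, 3], [0, 0, 0]))
        assert km.times.size == 0
        assert km.at(2.5) == 1.0

    def test_hand_product_limit(self):
        km = km_estimate(SurvivalData([1, 2, 3], [1, 0, 1]))
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2.5) == pytest.approx(2 / 3)  # censoring does not drop the curve
        assert km.at(3) == pytest.approx(0.0)

    def test_mass_event_drops_to_zero(self):
        km = km_estimate(SurvivalData([5, 5, 5, 5], [1, 1, 1, 1]))
        assert km.at(5) == 0.0

    def test_curve_monotone_from_one(self, bundle):
        clin = bundle.clinical.dropna(subset=["time", "event"])
        km = km_estimate(SurvivalData(clin["time"].to_numpy(), clin["event"].to_numpy(int)))
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert km.survival[0] <= 1.0


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        a = SurvivalData([1, 2, 3, 4], [1, 0, 1, 1])
        res = logrank_test(a, SurvivalData(a.time.copy(), a.event.copy()))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        # O-E = 0.2666..., V = 0.96222... tabulated by hand over 4 event times
        a = SurvivalData([1, 3, 5], [1, 0, 1])
        b = SurvivalData([2, 4, 6], [1, 1, 0])
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(0.0739030023094688, abs=1e-10)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        ta = rng.exponential(1, 40)
        tb = rng.exponential(2, 35)
        ea = (rng.random(40) < 0.7).astype(int)
        eb = (rng.random(35) < 0.7).astype(int)
        ours = logrank_test(SurvivalData(ta, ea), SurvivalData(tb, eb))
        ref = ll_logrank(ta, tb, ea, eb)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test(SurvivalData([1], [0]), SurvivalData([2], [0]))


class TestCoxFit:
    def test_four_subject_closed_form(self):
        # score equation reduces to e^{2 beta} = 2 -> beta = ln sqrt(2)
        data = SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])
        fit = cox_fit(data, np.array([[1.0], [0.0], [1.0], [0.0]]))
        assert fit.beta[0] == pytest.approx(np.log(np.sqrt(2)), abs=1e-10)
        assert fit.hr[0] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_partial_likelihood_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            n = int(rng.integers(5, 13))
            t = rng.exponential(1, n)  # continuous -> tie-free
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() == 0:
                continue
            X = rng.normal(size=(n, 2))
            beta = rng.normal(scale=0.5, size=2)
            ours = breslow_loglik(beta, t, e, X)
            oracle = brute_force_breslow(beta, t, e, X)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matches_lifelines_tie_free(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        n = 150
        X = rng.normal(size=(n, 2))
        t = rng.exponential(50 * np.exp(-0.5 * X[:, 0] + 0.3 * X[:, 1]))
        e = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        fit = cox_fit(SurvivalData(t, e), X, ["a", "b"])
        assert fit.beta == pytest.approx(ref.params_.values, abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_.values, abs=1e-5)

    def test_sd_rescaling_identity(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(2, 3, n)
        t = rng.exponential(np.exp(-0.3 * (x - x.mean()) / x.std(ddof=1)))
        e = np.ones(n, dtype=int)
        data = SurvivalData(t, e)
        sd = x.std(ddof=1)
        fit_raw = cox_fit(data, x[:, None])
        fit_sd = cox_fit(data, ((x - x.mean()) / sd)[:, None])
        assert fit_sd.beta[0] == pytest.approx(fit_raw.beta[0] * sd, abs=1e-7)

    def test_ci_contains_hr(self, bundle):
        data, X, names, _ = build_design(bundle.clinical, bundle.scores)
        fit = cox_fit(data, X, names)
        assert np.all(fit.ci_low <= fit.hr)
        assert np.all(fit.hr <= fit.ci_high)

    def test_constant_covariate_named_in_error(self):
        data = SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])
        X = np.column_stack([np.ones(4), [1.0, 0, 1, 0]])
        with pytest.raises(ValueError, match="intercept"):
            cox_fit(data, X, ["intercept", "x"])

    def test_separation_diagnosed(self):
        # perfect separation: covariate orders exactly with failure order
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20, dtype=int)
        x = -t  # higher x -> earlier death, monotone likelihood
        with pytest.raises(ValueError, match="(converge|separation)"):
            cox_fit(SurvivalData(t, e), x[:, None])

    def test_no_events_error(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(SurvivalData([1, 2], [0, 0]), np.array([[1.0], [0.0]]))


class TestSplitGroups:
    def test_even_median_split(self):
        labels = split_groups([1, 2, 3, 4])
        assert (labels == "low").sum() == 2 and (labels == "high").sum() == 2

    def test_value_at_median_goes_low(self):
        labels = split_groups([1, 2, 2, 3])
        assert labels[1] == "low" and labels[2] == "low"

    def test_tertile(self):
        labels = split_groups(np.arange(9), method="tertile")
        assert sorted(set(labels)) == ["high", "low", "mid"]

    def test_constant_error(self):
        with pytest.raises(ValueError):
            split_groups([2, 2, 2])


class TestMaxstat:
    def test_recovers_constructed_cutpoint(self):
        rng = np.random.default_rng(9)
        n = 120
        values = rng.uniform(0, 1, n)
        # subjects above 0.5 survive long, below die early
        t = np.where(values > 0.5, rng.exponential(50, n), rng.exponential(2, n))
        e = np.ones(n, dtype=int)
        out = maxstat_cutpoint(values, SurvivalData(np.maximum(t, 0.01), e), seed=1)
        assert abs(out["cutpoint"] - 0.5) < 0.12
        assert all(p < 0.05 for p in out["heldout_p"][:3])

    def test_too_many_folds_error(self):
        with pytest.raises(ValueError, match="fold"):
            maxstat_cutpoint(
                np.arange(10.0), SurvivalData(np.arange(1.0, 11.0), np.ones(10, int)), folds=10
            )


class TestRcs:
    def test_basis_dimensions_and_linearity_outside_knots(self):
        x = np.linspace(-5, 5, 200)
        basis = rcs_basis(x, np.array([-1.0, 0.0, 1.0]))
        assert basis.shape == (200, 2)
        # beyond the boundary knots the nonlinear column must be linear in x
        right = x > 1.5
        slope = np.diff(basis[right, 1]) / np.diff(x[right])
        assert np.allclose(slope, slope[0], atol=1e-8)

    def test_lr_statistic_nonnegative_nested(self, bundle):
        data, X, names, kept = build_design(bundle.clinical, bundle.scores)
        out = rcs_lr_test(data, X[:, 0], covariates=X[:, 1:])
        assert out["lr_statistic"] >= 0
        assert out["df"] == 1
        assert 0 < out["p"] <= 1

    def test_detects_strong_quadratic_hazard(self):
        rng = np.random.default_rng(21)
        n = 400
        x = rng.normal(size=n)
        lp = 1.2 * x**2  # strongly non-linear log-hazard
        t = rng.exponential(np.exp(-lp))
        data = SurvivalData(np.maximum(t, 1e-9), np.ones(n, int))
        out = rcs_lr_test(data, x)
        assert out["p"] < 0.01

    def test_degenerate_knots_error(self):
        x = np.r_[np.zeros(50), 1.0, 2.0]
        data = SurvivalData(np.arange(1.0, 53.0), np.ones(52, int))
        with pytest.raises(ValueError, match="knots"):
            rcs_lr_test(data, x)


class TestPhDiagnostics:
    def test_residuals_sum_to_zero_at_mle(self, bundle):
        # score equation: Schoenfeld residuals sum to ~0 at beta-hat
        data, X, names, _ = build_design(bundle.clinical, bundle.scores)
        fit = cox_fit(data, X, names)
        eta = X @ fit.beta
        w = np.exp(eta - eta.max())
        total = np.zeros(X.shape[1])
        for u in np.unique(data.time[data.event == 1]):
            at_risk = data.time >= u
            xbar = (w[at_risk, None] * X[at_risk]).sum(axis=0) / w[at_risk].sum()
            for i in np.where((data.time == u) & (data.event == 1))[0]:
                total += X[i] - xbar
        assert total == pytest.approx(np.zeros(X.shape[1]), abs=1e-6)

    def test_report_shape_and_null_behavior(self, bundle):
        data, X, names, _ = build_design(bundle.clinical, bundle.scores)
        fit = cox_fit(data, X, names)
        rep = ph_diagnostics(fit, data, X)
        assert list(rep["covariate"]) == names
        assert ((rep["p"] > 0) & (rep["p"] <= 1)).all()

    def test_flags_reversing_effect(self):
        # effect reverses sign mid-follow-up -> non-proportional hazards
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 300
            x = rng.normal(size=n)
            # early hazard increases with x, late hazard decreases
            t1 = rng.exponential(np.exp(-1.5 * x))
            t2 = 1.0 + rng.exponential(np.exp(1.5 * x))
            t = np.where(t1 < 1.0, t1, t2)
            data = SurvivalData(np.maximum(t, 1e-9), np.ones(n, int))
            fit = cox_fit(data, x[:, None], ["x"])
            rep = ph_diagnostics(fit, data, x[:, None])
            hits += rep["p"].iloc[0] < 0.05
        assert hits >= 9

    def test_too_few_events_error(self, bundle):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0])
        fit = cox_fit(data, np.array([[0.3], [1.2], [-1.0]]))
        with pytest.raises(ValueError, match="events"):
            ph_diagnostics(fit, data, np.array([[0.3], [1.2], [-1.0]]))


class TestBuildDesign:
    def test_complete_case_filtering(self, bundle):
        data, X, names, kept = build_design(bundle.clinical, bundle.scores)
        complete = bundle.clinical.dropna(subset=["time", "event", "age_years", "sex", "stage"])
        merged = complete.join(bundle.scores.rename("s"), how="inner")
        assert data.n == len(merged)

    def test_stage_coding_sensitivity_overlapping_cis(self, bundle):
        d1, X1, n1, _ = build_design(bundle.clinical, bundle.scores, stage_coding="ordinal")
        fit1 = cox_fit(d1, X1, n1)
        d2, X2, n2, _ = build_design(bundle.clinical, bundle.scores, stage_coding="categorical")
        fit2 = cox_fit(d2, X2, n2)
        # predictor CIs from the two stage parameterizations overlap
        assert fit1.ci_low[0] <= fit2.ci_high[0] and fit2.ci_low[0] <= fit1.ci_high[0]

    def test_predictor_standardized_to_unit_sd(self, bundle):
        data, X, names, _ = build_design(bundle.clinical, bundle.scores)
        assert X[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
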