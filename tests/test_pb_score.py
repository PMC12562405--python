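import numpy as np
import pandas as pd
import pytest

from toxscore.dge import DGETable, run_dge
from toxscore.io_formats import ExpressionMatrix
from toxscore.pb_score import concordance, fit_score, signed_ssgsea, ssgsea_score
from toxscore.survival import split_groups


def toy_matrix(values: np.ndarray, genes, n_tumor, n_normal=0) -> ExpressionMatrix:
    cols = [f"TCGA-TT-{i:04d}-01" for i in range(n_tumor)]
    cols += [f"TCGA-TT-{i + n_tumor:04d}-11" for i in range(n_normal)]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=cols))


def toy_dge(genes, log2fc) -> DGETable:
    frame = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "t": 1.0,
            "df": 10.0,
            "p": 0.01,
            "q": 0.02,
            "significant": True,
            "strict": False,
        }
    )
    return DGETable(frame=frame)


class TestFitScore:
    def test_single_gene_score_is_its_zscore(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 2, size=(1, 10))
        m = toy_matrix(x, ["A"], 10)
        model = fit_score(m, ["A"], toy_dge(["A"], [1.0]))
        z = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        assert model.scores_raw == pytest.approx(z, abs=1e-12)

    def test_flipping_signs_negates_scores(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 12))
        genes = list("ABCD")
        m = toy_matrix(x, genes, 12)
        up = fit_score(m, genes, toy_dge(genes, [1, 2, 0.5, 1.5]))
        down = fit_score(m, genes, toy_dge(genes, [-1, -2, -0.5, -1.5]))
        assert up.scores_raw == pytest.approx(-down.scores_raw, abs=1e-12)

    def test_two_gene_hand_example(self):
        # raw S_i = (sign_A z_A + sign_B z_B)/2, signs from the log2fc direction
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 6))
        m2 = toy_matrix(x, ["A", "B"], 6)
        model2 = fit_score(m2, ["A", "B"], toy_dge(["A", "B"], [2.0, -0.3]))
        za = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        zb = (x[1] - x[1].mean()) / x[1].std(ddof=1)
        assert model2.scores_raw == pytest.approx((za - zb) / 2, abs=1e-12)

    def test_zero_lfc_gene_excluded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 8))
        m = toy_matrix(x, ["A", "B"], 8)
        model = fit_score(m, ["A", "B"], toy_dge(["A", "B"], [1.0, 0.0]))
        assert model.genes == ["A"]

    def test_standardized_scores_mean0_sd1(self, bundle):
        s = bundle.score_model.scores_sd_units
        assert s.mean() == pytest.approx(0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_affine_invariance(self, bundle):
        # per-gene affine map a*x+b (a>0) leaves the composite unchanged
        rng = np.random.default_rng(4)
        values = bundle.matrix.values.copy()
        genes = bundle.score_model.genes
        a = rng.uniform(0.5, 3.0, size=len(genes))
        b = rng.normal(0, 10, size=len(genes))
        values.loc[genes] = values.loc[genes].to_numpy() * a[:, None] + b[:, None]
        m2 = ExpressionMatrix(values=values)
        model2 = fit_score(m2, genes, bundle.dge)
        assert model2.scores_sd_units == pytest.approx(bundle.score_model.scores_sd_units, abs=1e-9)

    def test_gene_order_invariance(self, bundle):
        genes = list(bundle.score_model.genes)
        model2 = fit_score(bundle.matrix, genes[::-1], bundle.dge)
        assert model2.scores_sd_units == pytest.approx(bundle.score_model.scores_sd_units, abs=1e-12)

    def test_median_split_balanced(self, bundle):
        labels = split_groups(bundle.score_model.scores_sd_units)
        n_low = (labels == "low").sum()
        n_high = (labels == "high").sum()
        assert abs(n_low - n_high) <= 1

    def test_apply_reuses_frozen_parameters(self, bundle):
        applied = bundle.score_model.apply(bundle.matrix)
        assert applied.to_numpy() == pytest.approx(bundle.score_model.scores_sd_units, abs=1e-12)


class TestSsgsea:
    def _toy(self):
        # 4 genes; sample s1 puts the set at the top, s2 at the bottom
        x = np.array(
            [
                [4.0, 1.0],  # g1 in set
                [3.0, 2.0],  # g2 in set
                [2.0, 3.0],
                [1.0, 4.0],
            ]
        )
        return toy_matrix(x, ["g1", "g2", "g3", "g4"], 2)

    def test_top_ranked_set_scores_higher(self):
        m = self._toy()
        s = ssgsea_score(m, {"g1", "g2"})
        assert s.iloc[0] > s.iloc[1]

    def test_identical_samples_identical_scores(self):
        x = np.tile(np.array([[4.0], [3.0], [2.0], [1.0]]), (1, 2))
        m = toy_matrix(x, ["g1", "g2", "g3", "g4"], 2)
        s = ssgsea_score(m, {"g1", "g3"})
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    def test_alpha_zero_is_unweighted_ecdf(self):
        # with alpha=0 every in-set gene contributes weight 1: brute-force
        m = self._toy()
        s = ssgsea_score(m, {"g1", "g2"}, alpha=0.0)
        # sample 1 walk (desc): g1*, g2*, g3, g4 -> ecdf_in - ecdf_out summed
        expected1 = (0.5 - 0) + (1.0 - 0) + (1.0 - 0.5) + (1.0 - 1.0)
        expected2 = (0 - 0.5) + (0 - 1.0) + (0.5 - 1.0) + (1.0 - 1.0)
        rng = max(expected1, expected2) - min(expected1, expected2)
        norm = [(v - min(expected1, expected2)) / rng for v in (expected1, expected2)]
        centered = [v - np.mean(norm) for v in norm]
        assert s.to_numpy() == pytest.approx(centered, abs=1e-12)

    def test_full_coverage_set_error(self):
        m = self._toy()
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(m, {"g1", "g2", "g3", "g4"})

    def test_signed_combination_directions(self):
        m = self._toy()
        s_up = signed_ssgsea(m, ["g1", "g2"], [])
        s_dn = signed_ssgsea(m, [], ["g1", "g2"])
        assert s_up.to_numpy() == pytest.approx(-s_dn.to_numpy())


class TestConcordance:
    def test_perfect_and_inverse(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance(a, a) == pytest.approx(1.0)
        assert concordance(a, -a) == pytest.approx(-1.0)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            concordance([1, 2, 3], [5, 5, 5])

    def test_fixture_composite_vs_ssgsea(self, bundle):
        lfc = bundle.dge.frame.set_index("gene")["log2fc"]
        genes = bundle.score_model.genes
        up = [g for g in genes if lfc[g] > 0]
        down = [g for g in genes if lfc[g] < 0]
        ss = signed_ssgsea(bundle.matrix, up, down)
        r = concordance(bundle.scores.to_numpy(), ss.loc[bundle.scores.index].to_numpy())
        assert r > 0.9
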