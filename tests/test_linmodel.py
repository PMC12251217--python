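"""Design-matrix linear models, variance moderation, contrast tests."""

import numpy as np
import pandas as pd
import pytest

from nrseqkit.linmodel import (
    LinearModelSpec,
    average_and_regularize,
    compare_parameters,
    contrast_vector,
    design_matrix,
    estimate_group_sds,
    fit_feature_lm,
    regularize_se,
)
from nrseqkit.validation import glm_calibration, interaction_identity


def _long_values(Y, samples, se=0.05, n=100):
    nf, ns = Y.shape
    return pd.DataFrame({
        "feature": np.repeat([f"g{i}" for i in range(nf)], ns),
        "sample": np.tile(samples, nf),
        "y": Y.ravel(), "se": se, "n": n,
    })


@pytest.fixture()
def two_condition_meta():
    return pd.DataFrame({"sample": [f"s{i}" for i in range(6)],
                         "condition": ["A"] * 3 + ["B"] * 3})


class TestDesignMatrix:
    def test_single_factor_is_cell_means(self, two_condition_meta):
        X = design_matrix("~condition", two_condition_meta)
        assert list(X.columns) == ["condition[A]", "condition[B]"]
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_interaction_only_is_cell_means_of_cells(self):
        meta = pd.DataFrame({"sample": list("abcd"),
                             "f1": ["x", "x", "y", "y"],
                             "f2": ["u", "v", "u", "v"]})
        X = design_matrix("~f1:f2", meta)
        assert X.shape == (4, 4)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_star_formula_keeps_intercept(self):
        meta = pd.DataFrame({"sample": list("abcd") * 2,
                             "f1": ["x", "x", "y", "y"] * 2,
                             "f2": ["u", "v", "u", "v"] * 2})
        X = design_matrix("~f1*f2", meta)
        assert "Intercept" in X.columns
        assert any(":" in c for c in X.columns)

    def test_rank_deficiency_rejected(self):
        meta = pd.DataFrame({"sample": list("abcd"),
                             "f1": ["x", "x", "y", "y"],
                             "f2": ["u", "u", "v", "v"]})  # f2 aliases f1
        with pytest.raises(ValueError, match="rank deficient"):
            design_matrix("~f1 + f2", meta)


class TestFitFeatureLM:
    def test_cell_means_equivalence(self, two_condition_meta):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 6))
        vals = _long_values(Y, two_condition_meta["sample"])
        fit = fit_feature_lm(vals, two_condition_meta,
                             LinearModelSpec("~condition", "y", "se"))
        order = [int(f[1:]) for f in fit.features]  # features sort as strings
        means_A = Y[order, :3].mean(axis=1)
        means_B = Y[order, 3:].mean(axis=1)
        jA = fit.coef_names.index("condition[A]")
        jB = fit.coef_names.index("condition[B]")
        assert np.allclose(fit.coef[:, jA], means_A, atol=1e-10)
        assert np.allclose(fit.coef[:, jB], means_B, atol=1e-10)

    def test_noise_free_residuals_zero_and_se_propagated(self, two_condition_meta):
        Y = np.tile([[1.0, 1.0, 1.0, 4.0, 4.0, 4.0]], (3, 1))
        vals = _long_values(Y, two_condition_meta["sample"], se=0.2)
        fit = fit_feature_lm(vals, two_condition_meta,
                             LinearModelSpec("~condition", "y", "se"))
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)
        # se of a 3-sample mean with obs se 0.2: 0.2/sqrt(3)
        se = np.sqrt(fit.cov[0].diagonal())
        assert np.allclose(se, 0.2 / np.sqrt(3), atol=1e-12)

    def test_interaction_matches_cell_means_identity(self):
        out = interaction_identity(3)
        assert out["abs_deviation"] <= 1e-10


class TestGroupSds:
    def test_recovers_heteroskedastic_ratio(self):
        rng = np.random.default_rng(2)
        nf, reps = 1000, 4
        samples = [f"s{i}" for i in range(2 * reps)]
        meta = pd.DataFrame({"sample": samples,
                             "condition": ["A"] * reps + ["B"] * reps})
        Y = np.concatenate([
            rng.normal(0, 0.2, (nf, reps)),      # group A
            rng.normal(0, 0.6, (nf, reps)),      # group B: 3x the sd
        ], axis=1)
        vals = _long_values(Y, samples, se=1e-6)
        fit = fit_feature_lm(vals, meta, LinearModelSpec("~condition", "y", "se"))
        sds, dfs = estimate_group_sds(fit)
        ratio = (sds["condition[B]"].mean() / sds["condition[A]"].mean())
        assert ratio == pytest.approx(3.0, rel=0.3)
        assert dfs["condition[A]"] == reps - 1

    def test_pooled_when_no_grouping_possible(self):
        meta = pd.DataFrame({"sample": [f"s{i}" for i in range(8)],
                             "f1": ["x", "x", "y", "y"] * 2,
                             "f2": ["u", "v", "u", "v"] * 2})
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(5, 8))
        vals = _long_values(Y, meta["sample"])
        fit = fit_feature_lm(vals, meta, LinearModelSpec("~f1*f2", "y", "se"))
        sds, dfs = estimate_group_sds(fit)
        assert list(sds.columns) == ["pooled"]


class TestRegularizeSe:
    def test_variance_trend_slope(self):
        # var proportional to 1/coverage -> slope -1 on the log-log scale
        rng = np.random.default_rng(4)
        nf, reps = 800, 4
        coverage = pd.Series(rng.integers(20, 20000, nf).astype(float),
                             index=[f"g{i}" for i in range(nf)])
        true_sd = 3.0 / np.sqrt(coverage.to_numpy())
        resid = rng.normal(0, true_sd[:, None], (nf, reps))
        s2 = (resid**2).sum(axis=1) / (reps - 1)
        sds = pd.DataFrame({"g": np.sqrt(s2)}, index=coverage.index)
        dfs = pd.Series({"g": float(reps - 1)})
        _, _, trend = regularize_se(sds, dfs, coverage)
        logc = np.log(coverage.to_numpy())
        slope = np.polyfit(logc, np.log(trend["g"].to_numpy()), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_moderation_reduces_variance_mse(self):
        out = glm_calibration(7, n_features=400)
        assert out["moderated_variance_mse"] < out["raw_variance_mse"]

    def test_few_features_pass_through(self):
        sds = pd.DataFrame({"g": [0.5] * 5}, index=[f"g{i}" for i in range(5)])
        dfs = pd.Series({"g": 3.0})
        cov = pd.Series(100.0, index=sds.index)
        with pytest.warns(UserWarning, match="fewer than"):
            mod, d0, _ = regularize_se(sds, dfs, cov)
        assert np.allclose(mod["g"], sds["g"])


class TestCompareParameters:
    def test_contrast_is_difference_of_means(self, two_condition_meta):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(50, 6))
        vals = _long_values(Y, two_condition_meta["sample"])
        fit = average_and_regularize(vals, two_condition_meta,
                                     LinearModelSpec("~condition", "y", "se"))
        res = compare_parameters(fit, "condition[B] - condition[A]")
        order = [int(f[1:]) for f in res["feature"]]
        want = Y[order, 3:].mean(axis=1) - Y[order, :3].mean(axis=1)
        # moderated refit re-weights samples but equal weights within groups
        assert np.allclose(res["estimate"], want, atol=1e-8)

    def test_unknown_coefficient_rejected(self, two_condition_meta):
        rng = np.random.default_rng(6)
        vals = _long_values(rng.normal(size=(5, 6)), two_condition_meta["sample"])
        fit = average_and_regularize(vals, two_condition_meta,
                                     LinearModelSpec("~condition", "y", "se"))
        with pytest.raises(ValueError, match="unknown coefficient"):
            compare_parameters(fit, "condition[C] - condition[A]")

    def test_bh_adjustment_matches_reference(self):
        rng = np.random.default_rng(7)
        pvals = rng.uniform(size=200)
        # reference BH: independent step-up implementation
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        ref = np.minimum.accumulate(ranked[::-1])[::-1]
        ref_full = np.empty_like(ref)
        ref_full[order] = np.minimum(ref, 1.0)
        from statsmodels.stats.multitest import multipletests
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(padj, ref_full, atol=1e-12)
        assert np.all(padj >= pvals - 1e-12)

    @pytest.mark.parametrize("reps", [2, 3, 5])
    def test_null_fdr_controlled(self, reps):
        out = glm_calibration(100 + reps, n_features=1000, reps=reps)
        assert out["null_fdr"] <= 1.5 * 0.05 + 1e-12

    def test_log2_scaling(self, two_condition_meta):
        Y = np.tile([[0.0, 0, 0, np.log(2), np.log(2), np.log(2)]], (3, 1))
        vals = _long_values(Y, two_condition_meta["sample"])
        fit = average_and_regularize(vals, two_condition_meta,
                                     LinearModelSpec("~condition", "y", "se"))
        res = compare_parameters(fit, "condition[B] - condition[A]",
                                 log2_scale=True)
        assert np.allclose(res["estimate"], 1.0, atol=1e-8)


def test_contrast_vector_forms(two_condition_meta):
    rng = np.random.default_rng(8)
    vals = _long_values(rng.normal(size=(3, 6)), two_condition_meta["sample"])
    fit = average_and_regularize(vals, two_condition_meta,
                                 LinearModelSpec("~condition", "y", "se"))
    c1 = contrast_vector(fit, "condition[B] - condition[A]")
    c2 = contrast_vector(fit, {"condition[B]": 1.0, "condition[A]": -1.0})
    c3 = contrast_vector(fit, np.array([-1.0, 1.0]))
    assert np.allclose(c1, c2)
    assert np.allclose(c1, c3)
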