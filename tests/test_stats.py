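import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from dietmet import (
    FeatureTable, SimulationSpec, ValidationError, bh_adjust, generate_study,
    meba_t2, mixed_anova_interaction, oplsda_fit, partial_correlation,
    partial_correlation_matrix, ratio_marker, roc_auc, volcano,
)
from dietmet.evaluate import (
    auc_oracle, bh_oracle, hotelling_oracle, partial_corr_oracle, _meba_table,
)
from dietmet.preprocessing import paired_ratios, preprocess_matrix
from dietmet.stats import anova_delta
from conftest import noise_free_spec


class TestBhAdjust:
    def test_spec_vector(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def _ratio_table(values, arms):
    cols = [f"P{i}" for i in range(values.shape[1])]
    samples = pd.DataFrame({
        "participant_id": cols, "arm": arms,
        "age": 40.0, "sex": "F", "bmi": 25.0,
    }, index=pd.Index(cols, name="sample_id"))
    fids = [f"f{i}" for i in range(values.shape[0])]
    return FeatureTable(
        pd.DataFrame(values, index=fids, columns=cols),
        pd.DataFrame(index=pd.Index(fids, name="feature_id")),
        samples, kind="ratios",
    )


class TestVolcano:
    def test_identical_arm_distributions(self):
        vals = np.array([[1.0, 2.0, 4.0, 1.0, 2.0, 4.0]])
        t = _ratio_table(vals, ["W-P"] * 3 + ["P-W"] * 3)
        out = volcano(t)
        assert out.loc["f0", "fc"] == pytest.approx(1.0)
        assert out.loc["f0", "p"] == pytest.approx(1.0)
        assert not out.loc["f0", "significant"]

    def test_noise_free_planted_fc_exact(self):
        from dietmet import PlantedFeature
        spec = noise_free_spec(
            planted_features=[PlantedFeature(9, "plasma", "prudent-up", 2.0)]
        )
        plasma, _, _, _ = generate_study(spec)
        out = volcano(paired_ratios(plasma))
        assert out.loc[plasma.feature_ids[9], "fc"] == pytest.approx(2.0, rel=1e-9)

    def test_significance_needs_both_fc_and_p(self):
        rng = np.random.default_rng(0)
        strong = np.exp(np.concatenate([rng.normal(0.8, 0.05, 6),
                                        rng.normal(0.0, 0.05, 6)]))
        weak = np.exp(np.concatenate([rng.normal(0.05, 0.01, 6),
                                      rng.normal(0.0, 0.01, 6)]))
        t = _ratio_table(np.vstack([strong, weak]), ["W-P"] * 6 + ["P-W"] * 6)
        out = volcano(t)
        assert out.loc["f0", "significant"]          # fc > 1.3 and p < 0.05
        assert out.loc["f1", "p"] < 0.05
        assert not out.loc["f1", "significant"]      # fc below 1.3


class TestOplsda:
    def test_n_orth_zero_equals_direct_pls(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array(["A"] * 10 + ["B"] * 10)
        model = oplsda_fit(X, y, n_orth=0, cv_folds=5, n_perm=20, seed=0)
        y_num = np.where(y == "A", 1.0, -1.0)
        y_num -= y_num.mean()
        w = X.T @ y_num
        w /= np.linalg.norm(w)
        assert np.allclose(model.scores, X @ w, atol=1e-8)

    def test_perfectly_separated_single_feature(self):
        x = np.array([[1.0], [1.0], [1.0], [-1.0], [-1.0], [-1.0]])
        x = (x - x.mean()) / x.std(ddof=1)
        y = np.array(["A"] * 3 + ["B"] * 3)
        model = oplsda_fit(x, y, n_orth=0, cv_folds=3, n_perm=20, seed=0)
        assert model.r2y >= 0.99
        assert abs(model.splot["correlation"].iloc[0]) == pytest.approx(1.0, abs=1e-9)

    def test_r2y_invariant_under_feature_permutation_and_sign_flip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 10))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array(["A", "B"] * 12)
        m1 = oplsda_fit(X, y, n_orth=1, cv_folds=4, n_perm=10, seed=1)
        perm = rng.permutation(10)
        flip = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        m2 = oplsda_fit(X[:, perm] * flip, y, n_orth=1, cv_folds=4, n_perm=10, seed=1)
        assert m1.r2y == pytest.approx(m2.r2y, abs=1e-10)

    def test_q2_bounded_by_r2y_and_strong_effect_detected(self):
        plasma, _, _, _ = generate_study(SimulationSpec(seed=7))
        prep = preprocess_matrix(plasma, matrix="plasma")
        t = prep["ratios_scaled"]
        model = oplsda_fit(t.responses.T, t.samples["arm"].to_numpy(),
                           n_orth=1, cv_folds=7, n_perm=99, seed=7)
        assert model.q2 <= model.r2y + 1e-9
        assert model.r2y > 0.84 and model.q2 > 0.2
        assert model.perm_p < 0.05

    def test_n_orth_exceeding_rank_raises(self):
        x = np.array([[1.0], [0.5], [-1.0], [-0.5]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            oplsda_fit(x, y, n_orth=1, cv_folds=2, n_perm=5, seed=0)


class TestMebaT2:
    def test_identical_arm_profiles_give_zero(self):
        prof = np.array([[0.0, 1.0], [0.5, 1.5], [1.0, 2.0]])
        a = np.stack([prof])          # 1 feature, 3 subjects
        res = meba_t2(_meba_table(a, a), prior_df=0.0)
        assert res["t2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_nu0_matches_longhand_hotelling(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=(3, 5, 2))
            b = rng.normal(0.5, 1.0, size=(3, 6, 2))
            res = meba_t2(_meba_table(a, b), prior_df=0.0)
            for i in range(3):
                assert res["t2"].iloc[i] == pytest.approx(
                    hotelling_oracle(a[i], b[i]), abs=1e-8)

    def test_singular_covariance_raises(self):
        a = np.zeros((1, 3, 2))
        a[0, :, 1] = [0.0, 2.0, 0.0]
        b = np.ones((1, 3, 2))
        b[0, :, 1] = [1.0, 3.0, 1.0]
        with pytest.raises(ValidationError, match="singular"):
            meba_t2(_meba_table(a, b), prior_df=0.0)

    def test_planted_features_rank_top(self, default_study):
        plasma, _, _, truth = default_study
        prep = preprocess_matrix(plasma, matrix="plasma")
        res = meba_t2(prep["glog"], prior_df=3.0)
        ranks = [res.loc[f, "rank"] for f in truth.planted_ids("plasma")]
        assert np.median(ranks) <= 0.1 * len(res)

    def test_moderation_shrinks_extreme_statistics(self, default_study):
        plasma, _, _, _ = default_study
        prep = preprocess_matrix(plasma, matrix="plasma")
        t0 = meba_t2(prep["glog"], prior_df=0.0)["t2"]
        t3 = meba_t2(prep["glog"], prior_df=3.0)["t2"]
        # ranking is preserved in spirit; the spread is damped
        assert t3.max() <= t0.max() * 1.5
        assert t3.std() < t0.std() * 1.2


class TestMixedAnova:
    def test_f_equals_t_squared_without_covariates(self):
        rng = np.random.default_rng(6)
        arm = np.repeat([1.0, 0.0], 12)
        delta = rng.normal(size=24) + 0.5 * arm
        f = float(anova_delta(delta[:, None], arm)["f"].iloc[0])
        t, p_t = sstats.ttest_ind(delta[arm == 1], delta[arm == 0], equal_var=True)
        assert f == pytest.approx(t * t, abs=1e-8)
        assert float(anova_delta(delta[:, None], arm)["p"].iloc[0]) == pytest.approx(
            p_t, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        n = 30
        arm = rng.integers(0, 2, n).astype(float)
        covs = pd.DataFrame({"age": rng.normal(45, 10, n),
                             "sex": rng.integers(0, 2, n).astype(float),
                             "bmi": rng.normal(27, 4, n)})
        delta = 0.4 * arm + 0.02 * covs["age"].to_numpy() + rng.normal(size=n)
        res = anova_delta(delta[:, None], arm, covs)
        X = sm.add_constant(np.column_stack([arm, covs.to_numpy()]))
        fit = sm.OLS(delta, X).fit()
        t_arm = fit.tvalues[1]
        assert float(res["f"].iloc[0]) == pytest.approx(t_arm ** 2, rel=1e-8)

    def test_collinear_covariate_raises(self):
        arm = np.repeat([1.0, 0.0], 5)
        covs = pd.DataFrame({"copy_of_arm": arm})
        with pytest.raises(ValidationError, match="collinear"):
            anova_delta(np.random.default_rng(0).normal(size=(10, 1)), arm, covs)

    def test_on_feature_table(self, default_study):
        plasma, _, _, truth = default_study
        prep = preprocess_matrix(plasma, matrix="plasma")
        res = mixed_anova_interaction(prep["glog"])
        assert (res["f"] >= 0).all()
        planted = truth.planted_ids("plasma")
        assert (res.loc[planted, "p"] < 0.05).mean() >= 0.5


class TestPartialCorrelation:
    def test_no_covariates_is_plain_pearson(self):
        res = partial_correlation([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.r == pytest.approx(1.0)

    def test_y_equal_to_covariate_flagged_undefined(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=20)
        res = partial_correlation(rng.normal(size=20), c, c[:, None])
        assert not res.ok and np.isnan(res.r)

    def test_matches_inverse_correlation_oracle(self):
        rng = np.random.default_rng(2)
        covs = rng.normal(size=(50, 2))
        x = covs @ [0.5, -0.3] + rng.normal(size=50)
        y = covs @ [0.2, 0.4] + 0.6 * x + rng.normal(size=50)
        res = partial_correlation(x, y, covs)
        assert res.r == pytest.approx(partial_corr_oracle(x, y, covs), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "x": rng.normal(size=40), "z1": rng.normal(size=40),
            "z2": rng.normal(size=40),
        })
        df["y"] = 0.5 * df["x"] + 0.3 * df["z1"] + rng.normal(size=40)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(df["x"], df["y"], df[["z1", "z2"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_known_partial_correlation_recovered(self):
        """Trivariate normal with known partial correlation 0.5."""
        rng = np.random.default_rng(4)
        n = 2000
        z = rng.normal(size=n)
        e1, e2 = rng.normal(size=n), rng.normal(size=n)
        rho = 0.5
        x = z + e1
        y = z + rho * e1 + np.sqrt(1 - rho * rho) * e2
        res = partial_correlation(x, y, z[:, None])
        assert abs(res.r - rho) < 0.05

    def test_matrix_version_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("uv"))
        C = pd.DataFrame(rng.normal(size=(30, 2)), columns=["age", "bmi"])
        r, p = partial_correlation_matrix(X, Y, C)
        for cx in X.columns:
            for cy in Y.columns:
                ref = partial_correlation(X[cx], Y[cy], C)
                assert r.loc[cx, cy] == pytest.approx(ref.r, abs=1e-10)
                assert p.loc[cx, cy] == pytest.approx(ref.p, abs=1e-10)

    def test_listwise_deletion_counts(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan, 12.0, 14.0])
        res = partial_correlation(x, y)
        assert res.n_used == 5


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4, 5, 6], ["n"] * 3 + ["p"] * 3, positive="p")
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_interleaved_case(self):
        res = roc_auc([1, 3, 2, 4], ["n", "n", "p", "p"], positive="p")
        assert res.auc == pytest.approx(0.75)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        r1 = roc_auc(vals, labels, positive="a")
        r2 = roc_auc(vals, labels, positive="b")
        assert r1.auc == pytest.approx(1.0 - r2.auc)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = np.round(rng.normal(0.3, 1, rng.integers(2, 7)), 1)
            neg = np.round(rng.normal(0, 1, rng.integers(2, 7)), 1)
            res = roc_auc(np.concatenate([pos, neg]),
                          ["p"] * len(pos) + ["n"] * len(neg), positive="p")
            assert res.auc == pytest.approx(auc_oracle(pos, neg), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], ["a", "a"])

    def test_ratio_marker_discriminates(self, default_study):
        plasma, _, _, truth = default_study
        planted = truth.planted_ids("plasma")
        up = [f for f in planted if truth.planted[f]["direction"] == "prudent-up"][-1]
        down = [f for f in planted if truth.planted[f]["direction"] == "western-up"][-1]
        from dietmet.preprocessing import impute_half_min, paired_ratios
        ratios = paired_ratios(impute_half_min(plasma))
        marker = ratio_marker(ratios, up, down)
        res = roc_auc(marker, ratios.samples["arm"], positive="W-P")
        assert res.auc > 0.82
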