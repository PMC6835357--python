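import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietmet import FeatureTable, SimulationSpec, ValidationError, generate_study
from dietmet.preprocessing import (
    autoscale, batch_correct, filter_detection, filter_qc_cv, glog_transform,
    impute_half_min, normalize_creatinine, normalize_internal_standard,
    paired_ratios, preprocess_matrix, qc_cvs,
)
from conftest import noise_free_spec


def _table(resp_rows, qc_flags=None, **meta_cols):
    n = len(resp_rows[0])
    cols = [f"s{i}" for i in range(n)]
    fids = [f"f{i}" for i in range(len(resp_rows))]
    samples = pd.DataFrame(
        {"is_qc": qc_flags or [False] * n, **meta_cols},
        index=pd.Index(cols, name="sample_id"),
    )
    return FeatureTable(
        pd.DataFrame(resp_rows, index=fids, columns=cols, dtype=float),
        pd.DataFrame(index=pd.Index(fids, name="feature_id")), samples,
    )


class TestNormalization:
    def test_internal_standard_ratio(self):
        t = _table([[2.0, 2.0], [4.0, 6.0]])
        out = normalize_internal_standard(t, "f0")
        assert list(out.responses.loc["f1"]) == [2.0, 3.0]
        assert list(out.responses.loc["f0"]) == [1.0, 1.0]
        assert bool(out.features.loc["f0", "excluded"])

    def test_identical_feature_becomes_ones(self):
        t = _table([[3.0, 5.0], [3.0, 5.0]])
        out = normalize_internal_standard(t, "f0")
        assert list(out.responses.loc["f1"]) == [1.0, 1.0]

    def test_missing_is_response_names_sample(self):
        t = _table([[2.0, np.nan], [4.0, 6.0]])
        with pytest.raises(ValidationError, match="s1"):
            normalize_internal_standard(t, "f0")

    def test_creatinine_dilution_invariance(self):
        # sample s1 is 2x more dilute; identical underlying excretion
        t = _table([[2.0, 4.0], [10.0, 20.0]])
        out = normalize_creatinine(t, "f0")
        assert out.responses.loc["f1", "s0"] == out.responses.loc["f1", "s1"]

    def test_creatinine_normalization_reduces_biological_cv(self):
        _, urine, _, _ = generate_study(SimulationSpec(seed=3, lod_quantile=0))
        cre = urine.features.index[urine.features["role"] == "creatinine"][0]
        metab_mask = urine.features["role"] == "metabolite"
        study = urine.study_ids()
        raw = urine.responses.loc[metab_mask, study]
        cv_raw = (raw.std(axis=1, ddof=1) / raw.mean(axis=1)).median()
        norm = normalize_creatinine(urine, cre).responses.loc[metab_mask, study]
        cv_norm = (norm.std(axis=1, ddof=1) / norm.mean(axis=1)).median()
        assert cv_norm < cv_raw

    def test_creatinine_one_everywhere_is_identity(self):
        t = _table([[1.0, 1.0], [7.0, 9.0]])
        out = normalize_creatinine(t, "f0")
        assert list(out.responses.loc["f1"]) == [7.0, 9.0]


class TestFilters:
    def _detection_table(self, n_present):
        row = [float(i + 1) for i in range(42)]
        for i in range(42 - n_present):
            row[i] = np.nan
        return _table([row])

    def test_31_of_42_removed_at_075(self):
        kept, summary = filter_detection(self._detection_table(31), 0.75)
        assert kept.n_features == 0
        assert summary.table.loc["f0", "detection_fraction"] == pytest.approx(31 / 42)

    def test_32_of_42_retained_at_075(self):
        kept, _ = filter_detection(self._detection_table(32), 0.75)
        assert kept.n_features == 1

    def test_all_pass_leaves_table_unchanged(self, small_table):
        kept, _ = filter_detection(small_table, 0.5)
        assert kept.equals(small_table)

    @pytest.mark.parametrize("qc_vals,expect_kept,expect_cv", [
        ([10.0, 10.0, 10.0], True, 0.0),
        ([8.0, 10.0, 12.0], True, 0.2),
        ([5.0, 10.0, 15.0], False, 0.5),
    ])
    def test_qc_cv_rule(self, qc_vals, expect_kept, expect_cv):
        t = _table([[1.0, 1.0, 1.0] + qc_vals],
                   qc_flags=[False] * 3 + [True] * 3)
        kept, summary = filter_qc_cv(t, 0.30)
        assert (kept.n_features == 1) is expect_kept
        assert summary.table.loc["f0", "qc_cv"] == pytest.approx(expect_cv)

    def test_single_qc_cv_undefined_retained(self):
        t = _table([[1.0, 1.0, 5.0]], qc_flags=[False, False, True])
        kept, summary = filter_qc_cv(t, 0.30)
        assert kept.n_features == 1
        assert summary.table.loc["f0", "reason"] == "cv-undefined"

    def test_filter_order_invariance(self, default_study):
        plasma = default_study[0]
        a1, _ = filter_detection(plasma, 0.75)
        a2, _ = filter_qc_cv(a1, 0.30)
        b1, _ = filter_qc_cv(plasma, 0.30)
        b2, _ = filter_detection(b1, 0.75)
        assert list(a2.feature_ids) == list(b2.feature_ids)


class TestImpute:
    def test_half_minimum_rule(self):
        t = _table([[4.0, np.nan, 8.0], [0.5, np.nan, 1.0]])
        out = impute_half_min(t)
        assert out.responses.loc["f0", "s1"] == 2.0
        assert out.responses.loc["f1", "s1"] == 0.25

    def test_no_missing_is_identity(self, small_table):
        full = small_table.copy()
        full.responses.loc["f2"] = 5.0
        full.responses.loc["f2", "P1_base"] = 5.0
        t = full.with_responses(full.responses.loc[["f1", "f3"]])
        assert impute_half_min(t).equals(t)

    def test_nonmissing_cells_never_change(self, default_study):
        plasma = default_study[0]
        out = impute_half_min(plasma)
        mask = plasma.responses.notna()
        assert np.array_equal(
            out.responses.to_numpy()[mask.to_numpy()],
            plasma.responses.to_numpy()[mask.to_numpy()],
        )
        assert not out.responses.isna().any().any()


class TestBatchCorrect:
    def test_single_batch_is_identity(self):
        t = _table([[2.0, 3.0, 4.0]], qc_flags=[True, False, False],
                   run_id=["b1"] * 3, injection_position=[1, 2, 3])
        corrected, model = batch_correct(t, anchoring="qc")
        assert np.allclose(corrected.responses, t.responses)
        assert np.allclose(model.shifts.to_numpy(), 0.0)

    def test_pure_location_shift_removed_exactly(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(2, 0.3, size=(4, 6)))
        vals[:, 3:] *= np.exp(0.5)
        t = _table(list(vals), qc_flags=[True, False, False] * 2,
                   run_id=["b1"] * 3 + ["b2"] * 3,
                   injection_position=[1, 2, 3] * 2)
        corrected, model = batch_correct(t, anchoring="grand-mean", shrink=False)
        logc = np.log(corrected.responses.to_numpy())
        assert np.max(np.abs(logc[:, :3].mean(1) - logc[:, 3:].mean(1))) < 1e-8

    def test_apply_then_invert_is_identity(self, default_study):
        urine = default_study[1]
        imputed = impute_half_min(urine)
        corrected, model = batch_correct(imputed, anchoring="qc")
        back = model.invert(corrected)
        assert np.allclose(
            np.log(back.responses.to_numpy()),
            np.log(imputed.responses.to_numpy()), atol=1e-10,
        )

    def test_missing_qc_in_qc_mode_raises(self):
        t = _table([[2.0, 3.0]], qc_flags=[False, False],
                   run_id=["b1", "b2"], injection_position=[1, 1])
        with pytest.raises(ValidationError, match="no QC"):
            batch_correct(t, anchoring="qc")


class TestTransforms:
    def test_glog_lambda_zero_is_log2(self):
        t = _table([[8.0, 2.0]])
        out = glog_transform(t, 0.0)
        assert list(out.responses.loc["f0"]) == [3.0, 1.0]

    def test_glog_closed_form_at_zero(self):
        t = _table([[0.0]])
        assert glog_transform(t, 2.0).responses.iloc[0, 0] == 0.0

    @given(st.lists(st.integers(0, 10 ** 9), min_size=2, max_size=6, unique=True),
           st.floats(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_glog_strictly_monotone(self, xs_int, lam):
        xs = sorted(x / 1000.0 for x in xs_int)
        t = _table([xs])
        out = glog_transform(t, lam).responses.to_numpy()[0]
        assert np.all(np.diff(out) > 0)

    def test_autoscale_values_and_properties(self):
        t = _table([[1.0, 2.0, 3.0]])
        out = autoscale(t)
        assert np.allclose(out.responses.loc["f0"], [-1.0, 0.0, 1.0])

    def test_autoscale_constant_feature_flagged(self):
        t = _table([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = autoscale(t)
        assert bool(out.features.loc["f0", "excluded"])
        assert out.responses.loc["f1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.responses.loc["f1"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestPairedRatios:
    def test_equal_timepoints_give_unit_ratios(self, small_table):
        t = impute_half_min(small_table)
        t.responses["P1_wk2"] = t.responses["P1_base"]
        t.responses["P2_wk2"] = t.responses["P2_base"]
        out = paired_ratios(t)
        assert np.allclose(out.responses.to_numpy(), 1.0)

    def test_noise_free_planted_ratio_exact(self):
        from dietmet import PlantedFeature
        spec = noise_free_spec(
            planted_features=[PlantedFeature(7, "plasma", "prudent-up", 2.0)]
        )
        plasma, _, _, truth = generate_study(spec)
        ratios = paired_ratios(plasma)
        arms = ratios.samples["arm"]
        fid = plasma.feature_ids[7]
        assert np.allclose(ratios.responses.loc[fid, arms == "W-P"], 2.0, rtol=1e-12)

    def test_participant_missing_timepoint_dropped(self, small_table):
        t = impute_half_min(small_table)
        t = t.with_responses(t.responses.drop(columns=["P2_wk2"]))
        out = paired_ratios(t)
        assert list(out.sample_ids) == ["P1"]


class TestPipelineComposition:
    def test_noise_free_pipeline_reproduces_fold_changes(self):
        spec = noise_free_spec()
        plasma, _, _, truth = generate_study(spec)
        prep = preprocess_matrix(plasma, matrix="plasma")
        ratios = prep["ratios"]
        arms = ratios.samples["arm"]
        for fid in truth.planted_ids("plasma"):
            fc = truth.planted[fid]["fold_change"]
            arm = "W-P" if truth.planted[fid]["direction"] == "prudent-up" else "P-W"
            assert np.allclose(ratios.responses.loc[fid, arms == arm], fc, rtol=1e-9)

    def test_counts_telescope(self, default_study):
        prep = preprocess_matrix(default_study[0], matrix="plasma")
        c = prep["counts"]
        assert c["input"] >= c["after_detection"] >= c["after_qc_cv"] >= c["analysis"]

    def test_urine_batch_correction_restores_qc_precision(self):
        """Heavy drift pushes QC CVs past the filter; correction pulls the
        median back inside the instrument's precision band."""
        import dataclasses
        spec = dataclasses.replace(
            SimulationSpec(seed=2), drift_per_injection=0.012, lod_quantile=0.0
        )
        _, urine, _, _ = generate_study(spec)
        is_f = urine.features.index[urine.features["role"] == "internal_standard"][0]
        cre = urine.features.index[urine.features["role"] == "creatinine"][0]
        norm = normalize_creatinine(normalize_internal_standard(urine, is_f), cre)
        metab = norm.with_responses(
            norm.responses.loc[norm.features["role"] == "metabolite"])
        assert float(qc_cvs(metab).median()) > 0.30
        corrected, _ = batch_correct(impute_half_min(metab), anchoring="qc")
        assert float(qc_cvs(corrected).median()) <= 0.12
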