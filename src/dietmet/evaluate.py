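"""Validation suites: independent oracles and end-to-end recovery checks.

Each suite recomputes a property of the pipeline from scratch against an
oracle that shares no code with the implementation it checks (exhaustive
enumeration, longhand matrix arithmetic, closed forms) or against the
synthetic generator's ground truth. Problem sizes are the package's own
validation scale and are documented in the methods note.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .calling import call_robust, cross_fluid_correlation
from .core_io import FeatureTable, PipelineConfig
from .diet_records import score_diet, summary_ttest
from .pipeline import analyse_matrix
from .preprocessing import (
    batch_correct, filter_detection, filter_qc_cv, impute_half_min,
    normalize_creatinine, normalize_internal_standard, preprocess_matrix, qc_cvs,
)
from .diet_records import participant_deltas
from .stats import anova_delta, bh_adjust, meba_t2, partial_correlation, roc_auc
from .synthetic import SimulationSpec, generate_study


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Exhaustive step-up BH: q_(i) = min_{j >= i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sp = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(1.0, sp[j] * m / (j + 1)) for j in range(i, m))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hotelling_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Longhand two-sample Hotelling T2 from explicit sums of outer products."""
    n1, n2 = a.shape[0], b.shape[0]
    am, bm = a.mean(axis=0), b.mean(axis=0)
    d = am - bm
    s = np.zeros((a.shape[1], a.shape[1]))
    for row in a:
        s += np.outer(row - am, row - am)
    for row in b:
        s += np.outer(row - bm, row - bm)
    s /= n1 + n2 - 2
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.inv(s) @ d)


def partial_corr_oracle(x: np.ndarray, y: np.ndarray, covs: np.ndarray) -> float:
    """Partial correlation via the inverse of the full correlation matrix."""
    m = np.column_stack([x, y, covs])
    omega = np.linalg.inv(np.corrcoef(m, rowvar=False))
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def auc_oracle(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by direct enumeration of all (pos, neg) pairs, ties count 1/2."""
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _meba_table(a: np.ndarray, b: np.ndarray) -> FeatureTable:
    """Pack profile arrays (subjects x 2) for several features into a table."""
    n1, n2 = a.shape[1], b.shape[1]
    n_feat = a.shape[0]
    pids = [f"S{i:02d}" for i in range(n1 + n2)]
    cols, vals, meta = [], [], []
    for j, pid in enumerate(pids):
        arm = "W-P" if j < n1 else "P-W"
        src = a[:, j, :] if j < n1 else b[:, j - n1, :]
        for t, tp in enumerate(("baseline", "week2")):
            cols.append(f"{pid}_{tp}")
            vals.append(src[:, t])
            meta.append((f"{pid}_{tp}", pid, arm, tp, False))
    resp = pd.DataFrame(np.column_stack(vals), columns=cols,
                        index=[f"f{i}" for i in range(n_feat)])
    samples = pd.DataFrame(
        meta, columns=["sample_id", "participant_id", "arm", "timepoint", "is_qc"]
    ).set_index("sample_id")
    feats = pd.DataFrame(index=resp.index)
    return FeatureTable(resp, feats, samples)


def oracle_suite(seed: int = 0) -> dict[str, float]:
    """Max deviations of each statistic from its independent oracle."""
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    # BH vs exhaustive step-up on 1000 random p-vectors
    dev = 0.0
    for _ in range(1000):
        m = int(rng.integers(1, 25))
        p = rng.random(m)
        dev = max(dev, float(np.max(np.abs(bh_adjust(p) - bh_oracle(p)))))
    out["bh_max_abs_dev"] = dev

    # moderated T2 at nu=0 vs longhand Hotelling, 100 random small instances
    dev = 0.0
    for _ in range(20):
        n1 = int(rng.integers(3, 8))
        n2 = int(rng.integers(3, 8))
        a = rng.normal(size=(5, n1, 2))
        b = rng.normal(0.3, 1.0, size=(5, n2, 2))
        res = meba_t2(_meba_table(a, b), prior_df=0.0)
        for i in range(5):
            t2_oracle = hotelling_oracle(a[i], b[i])
            dev = max(dev, abs(float(res["t2"].iloc[i]) - t2_oracle))
    out["meba_nu0_max_abs_dev"] = dev

    # partial correlation vs inverse-correlation-matrix formula
    dev = 0.0
    for _ in range(50):
        n = int(rng.integers(20, 60))
        k = int(rng.integers(1, 4))
        covs = rng.normal(size=(n, k))
        x = covs @ rng.normal(size=k) + rng.normal(size=n)
        y = covs @ rng.normal(size=k) + 0.5 * x + rng.normal(size=n)
        r_impl = partial_correlation(x, y, covs).r
        dev = max(dev, abs(r_impl - partial_corr_oracle(x, y, covs)))
    out["partial_corr_max_abs_dev"] = dev

    # AUC vs pairwise enumeration, all class-size pairs 2..6
    dev = 0.0
    for n1 in range(2, 7):
        for n2 in range(2, 7):
            for _ in range(4):
                pos = np.round(rng.normal(0.5, 1.0, n1), 1)  # rounding forces ties
                neg = np.round(rng.normal(0.0, 1.0, n2), 1)
                values = np.concatenate([pos, neg])
                labels = np.array(["pos"] * n1 + ["neg"] * n2)
                res = roc_auc(values, labels, positive="pos")
                dev = max(dev, abs(res.auc - auc_oracle(pos, neg)))
    out["roc_auc_max_abs_dev"] = dev

    # interaction F vs squared two-sample t (balanced, no covariates)
    dev = 0.0
    for _ in range(50):
        n = 2 * int(rng.integers(4, 12))
        arm = np.repeat([1.0, 0.0], n // 2)
        delta = rng.normal(size=n) + 0.4 * arm
        f = float(anova_delta(delta[:, None], arm)["f"].iloc[0])
        t, _ = sstats.ttest_ind(delta[arm == 1], delta[arm == 0], equal_var=True)
        dev = max(dev, abs(f - t * t))
    out["anova_f_t2_max_abs_dev"] = dev
    return out


# ---------------------------------------------------------------------------
# Null calibration (type-I error)
# ---------------------------------------------------------------------------

def null_spec(seed: int, n_features: int = 24) -> SimulationSpec:
    """Cohort with no planted effects: the generator's null configuration.

    Censoring and non-adherence are off so the check isolates the
    statistics' calibration from imputation artefacts.
    """
    return SimulationSpec(
        seed=seed, planted_features=[], n_cross_fluid_pairs=0,
        nonadherent_fraction=0.0, lod_quantile=0.0,
        n_features_plasma=n_features, n_features_urine=n_features,
    )


def null_calibration_suite(
    seed: int = 0, n_datasets: int = 200, n_perm: int = 200
) -> dict[str, float]:
    """OPLS-DA permutation type-I rate and ANOVA/volcano p uniformity."""
    cfg = PipelineConfig(n_permutations=n_perm)
    perm_ps, anova_p, volc_p = [], [], []
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 30)
    for i in range(n_datasets):
        plasma, _, nutrients, _ = generate_study(null_spec(int(base + i)))
        nd = participant_deltas(nutrients)
        prep = preprocess_matrix(plasma, matrix="plasma")
        res = analyse_matrix(prep, nd, cfg, seed=int(base + i))
        perm_ps.append(res["oplsda"].perm_p)
        anova_p += list(res["anova"]["p"])
        volc_p += list(res["volcano"]["p"])
    perm_ps = np.asarray(perm_ps)
    return {
        "oplsda_null_rejection_rate": float((perm_ps < 0.05).mean()),
        "anova_null_ks_p": float(sstats.kstest(anova_p, "uniform").pvalue),
        "volcano_null_ks_p": float(sstats.kstest(volc_p, "uniform").pvalue),
        "n_datasets": n_datasets,
    }


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def recovery_suite(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Robust-call sensitivity/specificity, MEBA ranks, cross-fluid recovery
    under generator defaults with known ground truth."""
    cfg = PipelineConfig()
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 30)
    sens, false_calls, rank_pct, xf_rs = [], [], [], []
    for i in range(n_seeds):
        s = int(base + i)
        plasma, urine, nutrients, truth = generate_study(SimulationSpec(seed=s))
        nd = participant_deltas(nutrients)
        n_called = n_planted = n_false = 0
        preps = {}
        for matrix, tbl in (("plasma", plasma), ("urine", urine)):
            prep = preprocess_matrix(tbl, matrix=matrix)
            preps[matrix] = prep
            res = analyse_matrix(prep, nd, cfg, seed=s, run_oplsda=False)
            calls = res["calls"]
            planted = [f for f in truth.planted_ids(matrix) if f in calls.index]
            n_planted += len(planted)
            n_called += int(calls.loc[planted, "robust"].sum())
            nonnull = set(truth.planted)  # planted + cross-fluid echoes
            nulls = [f for f in calls.index if f not in nonnull]
            n_false += int(calls.loc[nulls, "robust"].sum())
            meba = res["meba"]
            rank_pct += [float(meba.loc[f, "rank"]) / len(meba) for f in planted]
        sens.append(n_called / n_planted)
        false_calls.append(n_false)
        pairs = [(p, u) for p, u, _ in truth.cross_fluid_pairs]
        xf = cross_fluid_correlation(
            preps["plasma"]["normalized"], preps["urine"]["normalized"],
            pairs, log_scale=True,
        )
        xf_rs += list(xf["r"])
    return {
        "sensitivity": float(np.mean(sens)),
        "false_robust_calls_per_run": float(np.mean(false_calls)),
        "planted_meba_rank_median_pct": float(np.median(rank_pct)),
        "cross_fluid_r_mean": float(np.mean(xf_rs)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Batch correction
# ---------------------------------------------------------------------------

def batch_suite(seed: int = 0) -> dict[str, float]:
    """High-drift QC recovery and exact removal of a pure location shift."""
    # drift heavy enough to push QC CVs past the 0.30 filter
    spec = dataclasses.replace(SimulationSpec(seed=seed), drift_per_injection=0.012,
                               lod_quantile=0.0)
    _, urine, _, _ = generate_study(spec)
    is_f = urine.features.index[urine.features["role"] == "internal_standard"][0]
    cre_f = urine.features.index[urine.features["role"] == "creatinine"][0]
    norm = normalize_creatinine(normalize_internal_standard(urine, is_f), cre_f)
    metab = norm.with_responses(
        norm.responses.loc[norm.features["role"] == "metabolite"]
    )
    pre_cv = float(qc_cvs(metab).median())
    corrected, _ = batch_correct(impute_half_min(metab), anchoring="qc")
    post_cv = float(qc_cvs(corrected).median())

    # two batches offset by exactly +0.5 log units -> exact removal
    rng = np.random.default_rng(seed)
    n_feat, per_batch = 6, 5
    base = np.exp(rng.normal(3.0, 0.5, size=(n_feat, 2 * per_batch)))
    base[:, per_batch:] *= np.exp(0.5)
    cols = [f"s{i}" for i in range(2 * per_batch)]
    meta = pd.DataFrame({
        "participant_id": [None if i % per_batch == 0 else f"P{i}" for i in range(2 * per_batch)],
        "arm": [None if i % per_batch == 0 else "W-P" for i in range(2 * per_batch)],
        "timepoint": [None if i % per_batch == 0 else "baseline" for i in range(2 * per_batch)],
        "run_id": ["b1"] * per_batch + ["b2"] * per_batch,
        "injection_position": list(range(1, per_batch + 1)) * 2,
        "is_qc": [i % per_batch == 0 for i in range(2 * per_batch)],
    }, index=pd.Index(cols, name="sample_id"))
    table = FeatureTable(
        pd.DataFrame(base, index=[f"f{i}" for i in range(n_feat)], columns=cols),
        pd.DataFrame(index=[f"f{i}" for i in range(n_feat)]), meta,
    )
    corrected2, _ = batch_correct(table, anchoring="grand-mean", shrink=False)
    logc = np.log(corrected2.responses.to_numpy())
    b1 = logc[:, :per_batch].mean(axis=1)
    b2 = logc[:, per_batch:].mean(axis=1)
    return {
        "pre_correction_median_qc_cv": pre_cv,
        "post_correction_median_qc_cv": post_cv,
        "batch_shift_residual": float(np.max(np.abs(b1 - b2))),
    }


# ---------------------------------------------------------------------------
# Rule fixtures
# ---------------------------------------------------------------------------

def diet_score_fixtures() -> dict[str, object]:
    """The three published-threshold scoring cases."""
    all_prudent = score_diet({
        "poly_sat_ratio": 1.2, "sat_fat_pct": 6.0, "total_fiber": 30.0,
        "fruits_veg_servings": 6.0, "potassium": 3600.0,
    })
    all_western = score_diet({
        "poly_sat_ratio": 0.4, "sat_fat_pct": 17.0, "total_fiber": 8.0,
        "fruits_veg_servings": 4.0, "potassium": 3400.0,
    })
    boundary = score_diet({
        "poly_sat_ratio": 0.7, "sat_fat_pct": 10.0, "total_fiber": 20.0,
        "fruits_veg_servings": 5.0, "potassium": 3500.0,
    })
    return {
        "all_prudent": (all_prudent.prudent_points, all_prudent.western_points,
                        all_prudent.classification),
        "all_western": (all_western.prudent_points, all_western.western_points,
                        all_western.classification),
        "boundary": (boundary.prudent_points, boundary.western_points,
                     boundary.classification),
    }


def robust_call_fixtures() -> pd.DataFrame:
    """Three threshold cases of the robust-biomarker rule.

    a: 2 models + 2 nutrient hits -> robust; b: 1 model only -> not;
    c: 3 models but a single nutrient hit -> not.
    """
    idx = pd.Index(["a", "b", "c"], name="feature_id")
    meba = pd.DataFrame({"t2": [20.0, 20.0, 20.0],
                         "p_approx": [0.01, 0.01, 0.01]}, index=idx)
    anova = pd.DataFrame({"f": [8.0, 1.0, 8.0],
                          "p": [0.02, 0.60, 0.02]}, index=idx)
    volc = pd.DataFrame({"fc": [1.8, 1.1, 1.8],
                         "q": [0.20, 0.80, 0.01]}, index=idx)
    nutrients = ["fiber", "potassium", "fat"]
    r = pd.DataFrame(
        [[0.35, 0.41, 0.05], [0.10, 0.05, 0.02], [0.35, 0.10, 0.05]],
        index=idx, columns=nutrients,
    )
    p = pd.DataFrame(
        [[0.03, 0.01, 0.9], [0.5, 0.9, 0.9], [0.03, 0.5, 0.9]],
        index=idx, columns=nutrients,
    )
    return call_robust(meba, anova, volc, r, p, PipelineConfig())


def toy_filter_table() -> tuple[FeatureTable, set[str]]:
    """Ten features with designed missingness/CVs; returns (table, the set
    that must survive the 0.75 detection / 0.30 CV filters)."""
    n_study, n_qc = 20, 4
    cols = [f"s{i:02d}" for i in range(n_study)] + [f"qc{i}" for i in range(n_qc)]
    meta = pd.DataFrame({
        "participant_id": [f"P{i:02d}" for i in range(n_study)] + [None] * n_qc,
        "arm": ["W-P"] * n_study + [None] * n_qc,
        "timepoint": ["baseline"] * n_study + [None] * n_qc,
        "is_qc": [False] * n_study + [True] * n_qc,
    }, index=pd.Index(cols, name="sample_id"))
    rng = np.random.default_rng(7)
    rows, keep = [], set()
    fids = [f"f{i}" for i in range(10)]
    for i, fid in enumerate(fids):
        study = rng.uniform(50, 100, n_study)
        qc = np.full(n_qc, 80.0)
        drop_detection = i in (2, 5)   # detected in 14/20 = 0.70 < 0.75
        bad_cv = i in (3, 7)           # QC spread forces CV ~0.5
        if drop_detection:
            study[:6] = np.nan
        if bad_cv:
            qc = np.array([40.0, 80.0, 120.0, 80.0])  # CV = 32.66/80 = 0.408
        if not drop_detection and not bad_cv:
            keep.add(fid)
        rows.append(np.concatenate([study, qc]))
    table = FeatureTable(
        pd.DataFrame(rows, index=fids, columns=cols),
        pd.DataFrame(index=pd.Index(fids, name="feature_id")), meta,
    )
    return table, keep


def fixture_suite() -> dict[str, float]:
    """Boolean/count outcomes of all published-threshold fixtures."""
    ds = diet_score_fixtures()
    calls = robust_call_fixtures()
    table, designed = toy_filter_table()
    t1, _ = filter_detection(table, 0.75)
    t2, _ = filter_qc_cv(t1, 0.30)
    retained = set(t2.feature_ids)
    return {
        "diet_score_prudent_case_points": float(ds["all_prudent"][0]),
        "diet_score_western_case_points": float(ds["all_western"][1]),
        "diet_score_boundary_case_points": float(ds["boundary"][0] + ds["boundary"][1]),
        "robust_rule_fixture_verdicts_correct": float(
            (calls.loc["a", "robust"], calls.loc["b", "robust"],
             calls.loc["c", "robust"]) == (True, False, False)
        ),
        "toy_filter_retained_matches_design": float(retained == designed),
        "toy_filter_n_retained": float(len(retained)),
    }


def table1_ttest() -> dict[str, float]:
    """Pooled t-test on the printed insoluble-fiber arm summaries."""
    t, df, p = summary_ttest(14.0, 5.3, 24, -5.0, 3.5, 18)
    return {"insoluble_fiber_t": t, "insoluble_fiber_df": float(df),
            "insoluble_fiber_p": p}
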