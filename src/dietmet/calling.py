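"""Robust-biomarker decision rule, cross-fluid correlation, trajectories.

A feature is a *robust dietary biomarker* when it passes at least
``n_models_min`` of the three statistical models (moderated Hotelling T2
ranking, mixed diet x time ANOVA, and the FDR-adjusted univariate volcano
test) while also correlating (|r| > r_min, p < alpha) with at least
``n_nutrient_min`` nutrient categories from the self-reported records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_io import FeatureTable, ValidationError, PipelineConfig


# ---------------------------------------------------------------------------
# Robust calls
# ---------------------------------------------------------------------------

def call_robust(
    meba: pd.DataFrame,
    anova: pd.DataFrame,
    volcano: pd.DataFrame,
    pcorr_r: pd.DataFrame,
    pcorr_p: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Apply the robust-biomarker rule to aligned per-feature model results.

    ``meba``/``anova``/``volcano`` are the outputs of the corresponding
    model functions; ``pcorr_r``/``pcorr_p`` are features x nutrients
    partial-correlation matrices. All inputs must cover the same features.

    Returns one row per feature with the per-model pass flags, the nutrient
    hits, the robust verdict, and the top-five nutrient correlations by |r|
    (sign retained).
    """
    cfg = config or PipelineConfig()
    features = meba.index
    for name, df in (("anova", anova), ("volcano", volcano),
                     ("pcorr_r", pcorr_r), ("pcorr_p", pcorr_p)):
        missing = features.difference(df.index)
        if len(missing):
            raise ValidationError(
                f"feature(s) missing from {name} results: {list(missing[:5])}"
            )
    rows = []
    for fid in features:
        passed_meba = bool(meba.loc[fid, "p_approx"] < cfg.alpha)
        passed_anova = bool(anova.loc[fid, "p"] < cfg.alpha)
        passed_uni = bool(volcano.loc[fid, "q"] < cfg.q_threshold)
        n_models = int(passed_meba) + int(passed_anova) + int(passed_uni)
        r_row = pcorr_r.loc[fid]
        p_row = pcorr_p.loc[fid]
        hit_mask = (r_row.abs() > cfg.r_min) & (p_row < cfg.alpha)
        hits = [
            (nut, float(r_row[nut]), float(p_row[nut]))
            for nut in r_row.index[hit_mask]
        ]
        top5 = r_row.reindex(r_row.abs().sort_values(ascending=False).index)[:5]
        robust = n_models >= cfg.n_models_min and len(hits) >= cfg.n_nutrient_min
        rows.append({
            "feature_id": fid,
            "passed_meba": passed_meba,
            "passed_anova": passed_anova,
            "passed_univariate": passed_uni,
            "n_models_passed": n_models,
            "n_nutrient_hits": len(hits),
            "nutrient_hits": hits,
            "top5_nutrients": list(top5.index),
            "top5_r": [float(v) for v in top5.to_numpy()],
            "robust": robust,
            "meba_t2": float(meba.loc[fid, "t2"]),
            "anova_f": float(anova.loc[fid, "f"]),
            "volcano_fc": float(volcano.loc[fid, "fc"]),
            "volcano_q": float(volcano.loc[fid, "q"]),
        })
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# Cross-fluid correlation
# ---------------------------------------------------------------------------

def cross_fluid_correlation(
    plasma: FeatureTable,
    urine: FeatureTable,
    pairs: list[tuple[str, str]],
    log_scale: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of matched plasma/urine responses, both
    timepoints pooled.

    Samples are matched on (participant, timepoint). With
    ``log_scale=True`` the correlation is computed on log responses, which
    is the scale on which the generator defines cross-fluid coupling.
    """
    pmeta = plasma.samples.loc[plasma.study_ids()]
    umeta = urine.samples.loc[urine.study_ids()]
    pkey = pd.MultiIndex.from_frame(pmeta[["participant_id", "timepoint"]])
    ukey = pd.MultiIndex.from_frame(umeta[["participant_id", "timepoint"]])
    common = pkey.intersection(ukey)
    if len(common) == 0:
        raise ValidationError("no matched (participant, timepoint) samples")
    pcols = pd.Series(pmeta.index, index=pkey).loc[common].to_numpy()
    ucols = pd.Series(umeta.index, index=ukey).loc[common].to_numpy()
    rows = []
    for pfid, ufid in pairs:
        x = plasma.responses.loc[pfid, pcols].to_numpy(dtype=float)
        y = urine.responses.loc[ufid, ucols].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if log_scale:
            mask &= (x > 0) & (y > 0)
        x, y = x[mask], y[mask]
        if len(x) < 3:
            raise ValidationError(f"too few matched samples for pair {(pfid, ufid)}")
        if log_scale:
            x, y = np.log(x), np.log(y)
        r, p = sstats.pearsonr(x, y)
        rows.append({"plasma_feature": pfid, "urine_feature": ufid,
                     "r": float(r), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

def summarize_trajectories(
    table: FeatureTable,
    feature_ids: list[str] | None = None,
    outlier_z: float = 3.0,
) -> pd.DataFrame:
    """Per-feature, per-arm trajectory summaries on the response scale.

    For each feature: baseline and week-2 mean +/- SD per arm, the
    geometric-mean week2/baseline fold change per arm, the between-arm
    baseline t-test p (on log responses; flags pre-existing differences),
    and participants whose within-arm standardized log-ratio residual
    exceeds ``outlier_z`` (candidate non-adherers / misreporters).
    """
    feature_ids = list(feature_ids) if feature_ids is not None else list(table.feature_ids)
    meta = table.samples.loc[table.study_ids()]
    prof: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        prof.setdefault(row["participant_id"], {})[row["timepoint"]] = sid
    pids = sorted(p for p, t in prof.items() if {"baseline", "week2"} <= set(t))
    arms = meta.groupby("participant_id")["arm"].first().loc[pids]
    base_cols = [prof[p]["baseline"] for p in pids]
    wk2_cols = [prof[p]["week2"] for p in pids]

    rows = []
    for fid in feature_ids:
        base = table.responses.loc[fid, base_cols].to_numpy(dtype=float)
        wk2 = table.responses.loc[fid, wk2_cols].to_numpy(dtype=float)
        if np.isnan(base).any() or np.isnan(wk2).any() or (base <= 0).any():
            raise ValidationError(f"feature {fid!r} has missing/non-positive pairs")
        log_ratio = np.log(wk2 / base)
        rec: dict = {"feature_id": fid}
        outliers: list[str] = []
        for arm in ("W-P", "P-W"):
            m = (arms == arm).to_numpy()
            tag = arm.replace("-", "").lower()
            rec[f"baseline_mean_{tag}"] = base[m].mean()
            rec[f"baseline_sd_{tag}"] = base[m].std(ddof=1)
            rec[f"week2_mean_{tag}"] = wk2[m].mean()
            rec[f"week2_sd_{tag}"] = wk2[m].std(ddof=1)
            rec[f"fold_change_{tag}"] = float(np.exp(log_ratio[m].mean()))
            resid = log_ratio[m] - log_ratio[m].mean()
            sd = resid.std(ddof=1)
            if sd > 0:
                z = resid / sd
                outliers += [p for p, zz in zip(np.array(pids)[m], z)
                             if abs(zz) > outlier_z]
        _, p_base = sstats.ttest_ind(
            np.log(base[(arms == "W-P").to_numpy()]),
            np.log(base[(arms == "P-W").to_numpy()]),
            equal_var=True,
        )
        rec["baseline_p"] = float(p_base)
        rec["outliers"] = sorted(outliers)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("feature_id")
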