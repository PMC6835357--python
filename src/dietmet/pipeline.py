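"""End-to-end orchestration: simulate -> preprocess -> diet-score -> stats
-> robust calls, with a JSON run manifest.

A single global seed is expanded into independent per-stage substreams, so
adding a stage never perturbs the draws of earlier stages, and identical
(config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_robust, cross_fluid_correlation, summarize_trajectories
from .core_io import (
    FeatureTable, PipelineConfig, ValidationError,
    read_feature_table, write_feature_table,
)
from .diet_records import nutrient_deltas, participant_deltas, score_records
from .preprocessing import preprocess_matrix
from .stats import (
    meba_t2, mixed_anova_interaction, oplsda_fit, partial_correlation_matrix,
    volcano,
)
from .synthetic import SimulationSpec, generate_study


def _covariates_from(samples: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "age": samples["age"].astype(float),
        "sex": (samples["sex"] == "M").astype(float),
        "bmi": samples["bmi"].astype(float),
    }, index=samples.index)


def analyse_matrix(
    prep: dict,
    nutrient_delta: pd.DataFrame,
    config: PipelineConfig,
    seed: int,
    run_oplsda: bool = True,
) -> dict:
    """Statistical battery + robust calls for one preprocessed matrix.

    ``prep`` is the dict returned by :func:`preprocessing.preprocess_matrix`.
    """
    ratios = prep["ratios"]
    glogged = prep["glog"]
    arms = ratios.samples["arm"]
    covs = _covariates_from(ratios.samples)

    volc = volcano(ratios, arms, fc_min=config.fc_min, alpha=config.alpha,
                   glog_lambda=config.glog_lambda)
    meba = meba_t2(glogged, prior_df=config.meba_prior_df)
    anova = mixed_anova_interaction(glogged)

    log_ratios = pd.DataFrame(
        np.log2(ratios.responses.to_numpy()),
        index=ratios.feature_ids, columns=ratios.sample_ids,
    ).T  # participants x features
    deltas = nutrient_delta.loc[log_ratios.index]
    r_mat, p_mat = partial_correlation_matrix(log_ratios, deltas, covs)

    calls = call_robust(meba, anova, volc, r_mat, p_mat, config)

    opls = None
    if run_oplsda:
        opls = oplsda_fit(
            prep["ratios_scaled"].responses.T, arms.to_numpy(),
            n_orth=config.n_orth_components, cv_folds=config.cv_folds,
            n_perm=config.n_permutations, seed=seed,
        )
    return {
        "volcano": volc, "meba": meba, "anova": anova,
        "pcorr_r": r_mat, "pcorr_p": p_mat, "calls": calls, "oplsda": opls,
    }


def run_pipeline(
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    synthetic_spec: SimulationSpec | None = None,
    input_dir: str | Path | None = None,
    run_oplsda: bool = True,
) -> dict:
    """Run the full pipeline and write all stage outputs under ``out_dir``.

    Either ``synthetic_spec`` (generate a cohort) or ``input_dir``
    (read ``plasma.csv`` / ``urine.csv`` / ``nutrients.csv`` in core_io
    layout) must be provided. Returns the manifest (also written as
    ``manifest.json``).
    """
    config = (config or PipelineConfig()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(config.rng_seed),
        "config": dataclasses.asdict(config),
        "stages": {},
        "counts": {},
    }
    ss = np.random.SeedSequence(config.rng_seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    t0 = time.perf_counter()
    truth = None
    if synthetic_spec is not None:
        spec = dataclasses.replace(synthetic_spec, seed=stage_seeds[0])
        plasma, urine, nutrients, truth = generate_study(spec)
        write_feature_table(plasma, out / "plasma.csv")
        write_feature_table(urine, out / "urine.csv")
        nutrients.to_csv(out / "nutrients.csv", index=False, float_format="%.17g")
        (out / "ground_truth.json").write_text(
            json.dumps(truth.to_jsonable(), indent=1, sort_keys=True)
        )
    elif input_dir is not None:
        input_dir = Path(input_dir)
        plasma = read_feature_table(input_dir / "plasma.csv")
        urine = read_feature_table(input_dir / "urine.csv")
        nutrients = pd.read_csv(input_dir / "nutrients.csv")
    else:
        raise ValidationError("provide synthetic_spec or input_dir")
    manifest["stages"]["input"] = round(time.perf_counter() - t0, 3)

    # diet records
    t0 = time.perf_counter()
    scores = score_records(nutrients)
    scores.to_csv(out / "diet_scores.csv", index=False, float_format="%.17g")
    arms_map = (
        plasma.samples.loc[plasma.study_ids()]
        .groupby("participant_id")["arm"].first()
    )
    deltas_summary = nutrient_deltas(nutrients, arms_map)
    deltas_summary.to_csv(out / "nutrient_deltas.csv", float_format="%.17g")
    nd = participant_deltas(nutrients)
    manifest["stages"]["diet_records"] = round(time.perf_counter() - t0, 3)

    results = {}
    for matrix, table in (("plasma", plasma), ("urine", urine)):
        t0 = time.perf_counter()
        prep = preprocess_matrix(
            table, matrix=matrix,
            detection_fraction_min=config.detection_fraction_min,
            qc_cv_max=config.qc_cv_max, glog_lambda=config.glog_lambda,
        )
        manifest["counts"][matrix] = prep["counts"]
        prep["qc"].table.to_csv(out / f"{matrix}_qc_summary.csv", float_format="%.17g")
        write_feature_table(prep["corrected"], out / f"{matrix}_processed.csv")
        if prep["batch_model"] is not None:
            bm = prep["batch_model"]
            (out / f"{matrix}_batch_model.json").write_text(json.dumps({
                "anchoring": bm.anchoring,
                "shifts": {b: bm.shifts.loc[b].round(12).to_dict()
                           for b in bm.shifts.index},
            }, indent=1, sort_keys=True))
        res = analyse_matrix(prep, nd, config, seed=stage_seeds[1], run_oplsda=run_oplsda)
        res["volcano"].to_csv(out / f"{matrix}_volcano.csv", float_format="%.17g")
        res["meba"].to_csv(out / f"{matrix}_meba.csv", float_format="%.17g")
        res["anova"].to_csv(out / f"{matrix}_anova.csv", float_format="%.17g")
        res["pcorr_r"].to_csv(out / f"{matrix}_partialcorr_r.csv", float_format="%.17g")
        res["pcorr_p"].to_csv(out / f"{matrix}_partialcorr_p.csv", float_format="%.17g")
        calls = res["calls"].copy()
        calls["nutrient_hits"] = calls["nutrient_hits"].map(
            lambda h: ";".join(f"{n}:{r:.3f}:{p:.2e}" for n, r, p in h)
        )
        calls["top5_nutrients"] = calls["top5_nutrients"].map(";".join)
        calls["top5_r"] = calls["top5_r"].map(
            lambda v: ";".join(f"{x:.3f}" for x in v)
        )
        calls.to_csv(out / f"{matrix}_robust_calls.csv", float_format="%.17g")
        if res["oplsda"] is not None:
            m = res["oplsda"]
            (out / f"{matrix}_oplsda.json").write_text(json.dumps({
                "r2y": round(m.r2y, 10), "q2": round(m.q2, 10),
                "perm_p": round(m.perm_p, 10), "n_orth": m.n_orth,
            }, indent=1, sort_keys=True))
            m.splot.to_csv(out / f"{matrix}_oplsda_splot.csv", float_format="%.17g")
        robust_ids = list(res["calls"].index[res["calls"]["robust"]])
        if robust_ids:
            traj = summarize_trajectories(prep["corrected"], robust_ids)
            traj["outliers"] = traj["outliers"].map(";".join)
            traj.to_csv(out / f"{matrix}_trajectories.csv", float_format="%.17g")
        results[matrix] = res
        manifest["stages"][matrix] = round(time.perf_counter() - t0, 3)

    if truth is not None and truth.cross_fluid_pairs:
        pairs = [(p, u) for p, u, _ in truth.cross_fluid_pairs]
        xf = cross_fluid_correlation(plasma, urine, pairs, log_scale=True)
        xf.to_csv(out / "cross_fluid.csv", index=False, float_format="%.17g")

    for matrix in ("plasma", "urine"):
        c = manifest["counts"][matrix]
        if not (c["input"] >= c["after_detection"] >= c["after_qc_cv"] >= c["analysis"]):
            raise ValidationError("feature counts do not telescope")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
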