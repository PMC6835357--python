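"""Synthetic paired two-arm feeding-study generator with known ground truth.

Emulates a dietary-intervention metabolomics study: 42 participants in two
arms (24 switched to a Prudent diet, "W-P"; 18 switched to a Western diet,
"P-W"), paired baseline/week-2 samples in two biofluid matrices (fasting
plasma and single-spot urine), serial-injection runs of six study samples
plus one pooled QC, multiplicative signal drift across the injection
sequence, below-LOD censoring, per-participant nutrient records for 20
categories organised in two anti-correlated Prudent/Western blocks, and a
configurable set of planted diet-responsive metabolites whose week-2
responses are multiplied by a known fold change in the responding arm.

Abundances are log-normal: a CV is mapped to a log-scale sigma via
``sigma^2 = ln(1 + CV^2)``, which keeps responses strictly positive and
reproduces the right-skewed intensity distributions of real feature tables.
Urine responses carry a per-sample hydration/dilution factor (shared by
creatinine), plasma and urine both carry a per-injection efficiency factor
(shared by the spiked internal standard), so internal-standard and
creatinine normalization are exactly identifiable downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ARMS, FeatureTable, ValidationError

# ---------------------------------------------------------------------------
# Nutrient catalogue
# ---------------------------------------------------------------------------

#: (category, unit, block, baseline mean, baseline SD,
#:  delta mean W-P, delta SD W-P, delta mean P-W, delta SD P-W)
#: Arm-level intervention deltas are the study's printed summary statistics;
#: baselines describe a Western-leaning free-living cohort.
NUTRIENT_CATALOG: list[tuple[str, str, str, float, float, float, float, float, float]] = [
    ("insoluble_fiber",     "g/2000 kcal",        "prudent", 8.0,   3.0,  14.0,   5.3,    -5.0,   3.5),
    ("magnesium",           "mg/2000 kcal",       "prudent", 280.0, 70.0, 189.0,  89.0,   -134.0, 70.0),
    ("fruits_veg_servings", "servings/2000 kcal", "prudent", 3.5,   1.2,  3.6,    1.4,    -1.8,   1.3),
    ("total_fiber",         "g/2000 kcal",        "prudent", 18.0,  6.0,  16.6,   8.4,    -13.4,  8.1),
    ("sat_fat_pct",         "% energy",           "western", 12.0,  3.0,  -5.4,   3.2,    4.6,    2.4),
    ("potassium",           "mg/2000 kcal",       "prudent", 2800., 600., 1338.,  617.,   -854.,  667.),
    ("vegetable_cup_eq",    "cup eq./2000 kcal",  "prudent", 1.2,   0.5,  1.8,    0.80,   -0.91,  0.92),
    ("vitamin_e",           "mg/2000 kcal",       "prudent", 8.0,   3.0,  7.7,    5.3,    -7.0,   4.0),
    ("poly_sat_ratio",      "ratio",              "prudent", 0.60,  0.20, 0.47,   0.21,   -0.14,  0.18),
    ("vitamin_c",           "mg/2000 kcal",       "prudent", 75.0,  35.0, 149.0,  69.0,   -40.0,  54.0),
    ("soluble_fiber",       "g/2000 kcal",        "prudent", 4.0,   1.5,  3.9,    2.1,    -1.5,   1.5),
    ("fruit_cup_eq",        "cup eq./2000 kcal",  "prudent", 0.9,   0.5,  1.79,   0.93,   -0.92,  0.99),
    ("fat_pct",             "% energy",           "western", 35.0,  6.0,  -7.5,   5.6,    5.6,    5.6),
    ("sodium",              "mg/2000 kcal",       "western", 3300., 700., -694.,  590.,   754.,   658.),
    ("vitamin_a",           "ug/2000 kcal",       "prudent", 5500., 2500., 12973., 56344., -7847., 14060.),
    ("sugar_pct",           "% energy",           "prudent", 18.0,  5.0,  8.9,    5.4,    -1.5,   5.8),
    ("protein_pct",         "% energy",           "prudent", 16.0,  3.0,  1.9,    3.6,    -3.2,   2.7),
    ("carb_pct",            "% energy",           "prudent", 48.0,  8.0,  8.5,    7.8,    -0.35,  5.7),
    ("cholesterol",         "mg/2000 kcal",       "western", 300.,  100., -101.,  140.,   54.,    110.),
    ("trans_fat_pct",       "% energy",           "western", 1.1,   0.5,  -0.26,  0.55,   0.27,   0.23),
]

NUTRIENT_NAMES = [row[0] for row in NUTRIENT_CATALOG]
NUTRIENT_UNITS = {row[0]: row[1] for row in NUTRIENT_CATALOG}
NUTRIENT_BLOCKS = {row[0]: row[2] for row in NUTRIENT_CATALOG}

#: latent-factor loading of nutrient deltas on the per-participant diet-shift
#: intensity; 0.85 yields within/between-block |r| of about 0.72
BLOCK_LOADING = 0.85

IS_ROLE = "internal_standard"
CREATININE_ROLE = "creatinine"


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


# ---------------------------------------------------------------------------
# Specification and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedFeature:
    index: int                 # feature index within its matrix
    matrix: str                # "plasma" | "urine"
    direction: str             # "prudent-up" | "western-up"
    fold_change: float


def default_planted() -> list[PlantedFeature]:
    """Twelve planted biomarkers, six per matrix, fold changes 1.5-5.

    Four per matrix rise under the Prudent diet (the study's flagship
    markers were Prudent-responsive) and two under the Western diet.
    """
    fcs = [1.5, 2.0, 2.5, 3.0, 4.0, 5.0]
    dirs = ["prudent-up"] * 4 + ["western-up"] * 2
    plasma_idx = [5, 12, 23, 34, 47, 58]
    urine_idx = [5, 12, 23, 34, 47, 58]
    planted = [
        PlantedFeature(i, "plasma", d, fc)
        for i, d, fc in zip(plasma_idx, dirs, fcs)
    ]
    planted += [
        PlantedFeature(i, "urine", d, fc)
        for i, d, fc in zip(urine_idx, dirs, fcs)
    ]
    return planted


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults are the emulated study's conditions: 24 + 18 participants,
    80 plasma and 84 urine features (including the spiked internal standard
    and, for urine, creatinine), technical CV 10%, biological CVs 45%
    (plasma) and 70% (urine), modest per-injection drift, 5% below-LOD
    censoring, one expected non-adherent participant, and nutrient-response
    coupling r = 0.5.
    """

    n_wp: int = 24
    n_pw: int = 18
    n_features_plasma: int = 80
    n_features_urine: int = 84
    n_nutrients: int = 20
    planted_features: Sequence[PlantedFeature] | None = None
    technical_cv: float = 0.10
    is_technical_cv: float = 0.03        # abundant spiked standard
    creatinine_technical_cv: float = 0.04
    biological_cv_plasma: float = 0.45
    biological_cv_urine: float = 0.70
    within_subject_cv: float = 0.25      # week-to-week biological variation
    response_sd: float = 0.30            # log-scale spread of individual diet response
    efficiency_cv: float = 0.08          # per-injection factor shared by all features
    dilution_cv: float = 0.40            # urine hydration factor shared w/ creatinine
    drift_per_injection: float = 0.001
    lod_quantile: float = 0.05
    nonadherent_fraction: float = 1.0 / 42.0
    nutrient_effect_r: float = 0.5
    cross_fluid_r: float = 0.6
    n_cross_fluid_pairs: int = 2
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        for name in ("n_wp", "n_pw", "n_features_plasma", "n_features_urine", "n_nutrients"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("technical_cv", "biological_cv_plasma", "biological_cv_urine",
                     "within_subject_cv", "efficiency_cv", "dilution_cv",
                     "lod_quantile", "nonadherent_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name}={v} must be in [0, 1)")
        for pf in self.planted() :
            n = self.n_features_plasma if pf.matrix == "plasma" else self.n_features_urine
            if not (0 <= pf.index < n):
                raise ValidationError(f"planted index {pf.index} out of range for {pf.matrix}")
            if pf.fold_change <= 1.0:
                raise ValidationError("planted fold_change must be > 1")
            if pf.direction not in ("prudent-up", "western-up"):
                raise ValidationError(f"unknown direction {pf.direction!r}")
            if pf.matrix == "plasma" and pf.index == 0:
                raise ValidationError("plasma feature 0 is the internal standard")
            if pf.matrix == "urine" and pf.index in (0, 1):
                raise ValidationError("urine features 0/1 are creatinine and the internal standard")
        return self

    def planted(self) -> list[PlantedFeature]:
        if self.planted_features is None:
            return default_planted()
        return list(self.planted_features)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream scoring."""

    planted: dict[str, dict] = field(default_factory=dict)
    nonadherent: set[str] = field(default_factory=set)
    drift_factors: dict[str, pd.Series] = field(default_factory=dict)
    lod: dict[str, float] = field(default_factory=dict)
    arms: dict[str, str] = field(default_factory=dict)
    latent_shift: dict[str, float] = field(default_factory=dict)
    cross_fluid_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def planted_ids(self, matrix: str | None = None, primary_only: bool = True) -> list[str]:
        out = []
        for fid, info in self.planted.items():
            if matrix is not None and info["matrix"] != matrix:
                continue
            if primary_only and info.get("via") == "cross-fluid":
                continue
            out.append(fid)
        return out

    def to_jsonable(self) -> dict:
        return {
            "planted": self.planted,
            "nonadherent": sorted(self.nonadherent),
            "drift_factors": {m: s.to_dict() for m, s in self.drift_factors.items()},
            "lod": self.lod,
            "arms": self.arms,
            "latent_shift": self.latent_shift,
            "cross_fluid_pairs": [list(p) for p in self.cross_fluid_pairs],
        }


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

def _make_participants(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_wp + spec.n_pw
    pids = [f"P{i + 1:02d}" for i in range(n)]
    arms = ["W-P"] * spec.n_wp + ["P-W"] * spec.n_pw
    age = rng.integers(20, 70, size=n)
    sex = np.where(rng.random(n) < 0.64, "F", "M")
    bmi = np.clip(rng.normal(27.0, 4.0, size=n), 18.0, 45.0)
    return pd.DataFrame(
        {"arm": arms, "age": age, "sex": sex, "bmi": np.round(bmi, 1)}, index=pids
    )


def _make_feature_meta(matrix: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    prefix = "pl" if matrix == "plasma" else "ur"
    fids = [f"{prefix}_{i:03d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(fids, name="feature_id"))
    meta["name"] = [f"met_{prefix}_{i:03d}" for i in range(n)]
    meta["mz"] = np.round(rng.uniform(60.0, 500.0, size=n), 3)
    meta["rmt"] = np.round(rng.uniform(0.4, 1.8, size=n), 3)
    meta["ion_mode"] = rng.choice(["+", "-"], size=n)
    meta["platform"] = "MSI-CE-MS"
    meta["id_level"] = rng.integers(1, 5, size=n)
    meta["role"] = "metabolite"
    if matrix == "plasma":
        meta.iloc[0, meta.columns.get_loc("role")] = IS_ROLE
        meta.iloc[0, meta.columns.get_loc("name")] = "Cl-Tyr (IS)"
    else:
        meta.iloc[0, meta.columns.get_loc("role")] = CREATININE_ROLE
        meta.iloc[0, meta.columns.get_loc("name")] = "creatinine"
        meta.iloc[1, meta.columns.get_loc("role")] = IS_ROLE
        meta.iloc[1, meta.columns.get_loc("name")] = "Cl-Tyr (IS)"
    return meta


def _make_sample_meta(
    matrix: str, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Serial-injection layout: runs of 3 participant pairs + 1 QC (7 injections)."""
    prefix = "pl" if matrix == "plasma" else "ur"
    pids = list(participants.index)
    order = list(rng.permutation(pids))
    rows = []
    run = 0
    for start in range(0, len(order), 3):
        run += 1
        run_id = f"{prefix}_run{run:02d}"
        trio = order[start:start + 3]
        entries: list[tuple] = []
        for pid in trio:
            entries.append((f"{pid}_{prefix}_base", pid, "baseline"))
            entries.append((f"{pid}_{prefix}_wk2", pid, "week2"))
        qc_pos = int(rng.integers(0, len(entries) + 1))
        entries.insert(qc_pos, (f"QC_{prefix}_{run:02d}", None, None))
        for pos, (sid, pid, tp) in enumerate(entries, start=1):
            if pid is None:
                rows.append((sid, None, None, None, matrix, None, None, None,
                             run_id, pos, True))
            else:
                p = participants.loc[pid]
                rows.append((sid, pid, p["arm"], tp, matrix, p["age"], p["sex"],
                             p["bmi"], run_id, pos, False))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "participant_id", "arm", "timepoint", "matrix",
                 "age", "sex", "bmi", "run_id", "injection_position", "is_qc"],
    ).set_index("sample_id")
    return meta


def _effect_arm(direction: str) -> str:
    return "W-P" if direction == "prudent-up" else "P-W"


def _simulate_matrix(
    matrix: str,
    spec: SimulationSpec,
    participants: pd.DataFrame,
    latent_z: pd.Series,
    nonadherent: set[str],
    rng: np.random.Generator,
) -> tuple[FeatureTable, dict[str, dict], pd.Series]:
    """Returns (table, planted map for this matrix, per-sample log dilution)."""
    n_feat = spec.n_features_plasma if matrix == "plasma" else spec.n_features_urine
    bio_cv = spec.biological_cv_plasma if matrix == "plasma" else spec.biological_cv_urine
    feats = _make_feature_meta(matrix, n_feat, rng)
    samples = _make_sample_meta(matrix, participants, rng)

    fids = feats.index.to_numpy()
    sids = samples.index.to_numpy()
    pids = list(participants.index)
    n_p = len(pids)
    roles = feats["role"].to_numpy()
    is_metab = roles == "metabolite"

    sig_b = np.where(is_metab, _cv_to_sigma(bio_cv), 0.0)
    sig_w = np.where(is_metab, _cv_to_sigma(spec.within_subject_cv), 0.0)
    sig_t = np.full(n_feat, _cv_to_sigma(spec.technical_cv))
    sig_t[roles == IS_ROLE] = _cv_to_sigma(spec.is_technical_cv)
    sig_t[roles == CREATININE_ROLE] = _cv_to_sigma(spec.creatinine_technical_cv)
    if matrix == "urine":
        cre = roles == CREATININE_ROLE
        sig_b[cre] = 0.15
        sig_w[cre] = 0.10

    mu = rng.normal(np.log(500.0), 1.0, size=n_feat)
    mu[roles == IS_ROLE] = np.log(1000.0)
    mu[roles == CREATININE_ROLE] = np.log(2000.0)

    b = rng.normal(0.0, 1.0, size=(n_feat, n_p)) * sig_b[:, None]          # between-subject
    w = rng.normal(0.0, 1.0, size=(n_feat, n_p, 2)) * sig_w[:, None, None]  # within-subject

    # planted multiplicative week-2 effects, per participant
    planted_here = [p for p in spec.planted() if p.matrix == matrix]
    planted_map: dict[str, dict] = {}
    effect_log = np.zeros((n_feat, n_p))  # realised log effect at week 2
    r = spec.nutrient_effect_r
    z = latent_z.loc[pids].to_numpy()
    for pf in planted_here:
        fid = fids[pf.index]
        planted_map[fid] = {
            "matrix": matrix, "direction": pf.direction,
            "fold_change": pf.fold_change, "via": "planted",
        }
        het = spec.response_sd * (
            r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(0.0, 1.0, size=n_p)
        )
        arm_eff = _effect_arm(pf.direction)
        for j, pid in enumerate(pids):
            arm = participants.loc[pid, "arm"]
            if pid in nonadherent:
                arm = "P-W" if arm == "W-P" else "W-P"
            if arm == arm_eff:
                effect_log[pf.index, j] = np.log(pf.fold_change) + het[j]

    # assemble per-sample log responses
    p_index = {pid: j for j, pid in enumerate(pids)}
    t_index = {"baseline": 0, "week2": 1}
    eff_sig = _cv_to_sigma(spec.efficiency_cv)
    dil_sig = _cv_to_sigma(spec.dilution_cv)
    eta = rng.normal(0.0, eff_sig, size=len(sids))
    dil = rng.normal(0.0, dil_sig, size=len(sids)) if matrix == "urine" else np.zeros(len(sids))
    tech = rng.normal(0.0, 1.0, size=(n_feat, len(sids))) * sig_t[:, None]

    logx = np.empty((n_feat, len(sids)))
    fc_factor = np.ones((n_feat, len(sids)))
    is_qc = samples["is_qc"].to_numpy(dtype=bool)
    dilutes = is_metab | (roles == CREATININE_ROLE)  # IS is spiked post-dilution
    for s, sid in enumerate(sids):
        if is_qc[s]:
            logx[:, s] = mu + eta[s] + tech[:, s]
            continue
        j = p_index[samples.iloc[s]["participant_id"]]
        t = t_index[samples.iloc[s]["timepoint"]]
        logx[:, s] = mu + b[:, j] + w[:, j, t] + eta[s] + tech[:, s]
        logx[dilutes, s] += dil[s]
        if t == 1:
            fc_factor[:, s] = np.exp(effect_log[:, j])

    resp = pd.DataFrame(np.exp(logx) * fc_factor, index=feats.index, columns=samples.index)
    table = FeatureTable(resp, feats, samples)
    return table, planted_map, pd.Series(dil, index=samples.index)


def _couple_cross_fluid(
    plasma: FeatureTable,
    urine: FeatureTable,
    urine_dilution: pd.Series,
    truth: GroundTruth,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> None:
    """Rewrite selected urine features as noisy echoes of plasma planted features.

    The echo's standardized log deviation over matched study samples equals
    ``rho * (standardized plasma deviation) + sqrt(1-rho^2) * noise``, so the
    pooled log-scale Pearson correlation between the pair recovers ``rho``
    by construction; diet effects are inherited in attenuated form, which is
    how the same compound measured in two biofluids behaves.
    """
    rho = spec.cross_fluid_r
    n_pairs = spec.n_cross_fluid_pairs
    if n_pairs <= 0:
        return
    plasma_planted = [f for f, v in truth.planted.items()
                      if v["matrix"] == "plasma" and v["via"] == "planted"]
    plasma_planted = sorted(
        plasma_planted, key=lambda f: -truth.planted[f]["fold_change"]
    )[:n_pairs]
    # echo slots: last urine metabolite features, skipping planted ones
    urine_planted = set(truth.planted_ids("urine", primary_only=False))
    candidates = [f for f in urine.feature_ids[::-1]
                  if urine.features.loc[f, "role"] == "metabolite"
                  and f not in urine_planted]
    echo_ids = candidates[:len(plasma_planted)]

    # matched study samples by (participant, timepoint)
    pmeta = plasma.samples.loc[plasma.study_ids()]
    umeta = urine.samples.loc[urine.study_ids()]
    pkey = pd.MultiIndex.from_frame(pmeta[["participant_id", "timepoint"]])
    ukey = pd.MultiIndex.from_frame(umeta[["participant_id", "timepoint"]])
    common = pkey.intersection(ukey)
    p_by_key = pd.Series(pmeta.index, index=pkey)
    u_by_key = pd.Series(umeta.index, index=ukey)

    for pfid, ufid in zip(plasma_planted, echo_ids):
        src = np.log(plasma.responses.loc[pfid, p_by_key.loc[common]].to_numpy(float))
        sd = src.std(ddof=1)
        zsrc = (src - src.mean()) / sd if sd > 1e-12 else np.zeros_like(src)
        sig_u = _cv_to_sigma(spec.biological_cv_urine)
        mu_u = np.log(urine.responses.loc[ufid].median())
        noise = rng.normal(0.0, 1.0, size=len(common))
        logx = mu_u + sig_u * (rho * zsrc + np.sqrt(max(0.0, 1.0 - rho * rho)) * noise)
        # hydration dilution + technical noise as for any urine metabolite
        tech = rng.normal(0.0, _cv_to_sigma(spec.technical_cv), size=len(common))
        ucols = u_by_key.loc[common].to_numpy()
        logx = logx + urine_dilution.loc[ucols].to_numpy(float)
        urine.responses.loc[ufid, ucols] = np.exp(logx + tech)
        src_info = truth.planted[pfid]
        truth.planted[ufid] = {
            "matrix": "urine", "direction": src_info["direction"],
            "fold_change": float(src_info["fold_change"] ** rho),
            "via": "cross-fluid", "plasma_partner": pfid,
        }
        truth.cross_fluid_pairs.append((pfid, ufid, rho))


def _make_nutrients(
    spec: SimulationSpec,
    participants: pd.DataFrame,
    latent_z: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-period nutrient records with block structure and coupled deltas."""
    cats = NUTRIENT_CATALOG[: spec.n_nutrients]
    pids = list(participants.index)
    rows = []
    for pid in pids:
        arm = participants.loc[pid, "arm"]
        z = latent_z.loc[pid]
        base_row = {"participant_id": pid, "period": "baseline"}
        int_row = {"participant_id": pid, "period": "intervention"}
        for (cat, _unit, block, bmean, bsd, d_wp, s_wp, d_pw, s_pw) in cats:
            base = max(bmean + bsd * rng.normal(), 0.01 * bmean)
            dmean, dsd = (d_wp, s_wp) if arm == "W-P" else (d_pw, s_pw)
            # sign: +z for categories that increase under the assigned diet
            increases = (block == "prudent") == (arm == "W-P")
            sgn = 1.0 if increases else -1.0
            delta = dmean + dsd * (
                BLOCK_LOADING * sgn * z
                + np.sqrt(1.0 - BLOCK_LOADING ** 2) * rng.normal()
            )
            base_row[cat] = base
            int_row[cat] = max(base + delta, 0.0)
        rows.append(base_row)
        rows.append(int_row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_study(
    spec: SimulationSpec | None = None,
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort: (plasma, urine, nutrient records, truth).

    Deterministic under ``spec.seed``. Drift and below-LOD censoring are
    applied per ``spec`` (set ``drift_per_injection=0`` / ``lod_quantile=0``
    to disable).
    """
    spec = (spec or SimulationSpec()).validate()
    ss = np.random.SeedSequence(spec.seed)
    r_part, r_plasma, r_urine, r_nutr, r_cross = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    participants = _make_participants(spec, r_part)
    pids = list(participants.index)
    n_nonadh = int(round(spec.nonadherent_fraction * len(pids)))
    nonadherent = set(
        r_part.choice(pids, size=n_nonadh, replace=False)
    ) if n_nonadh else set()
    latent_z = pd.Series(r_part.normal(0.0, 1.0, size=len(pids)), index=pids)

    truth = GroundTruth(
        arms=participants["arm"].to_dict(),
        nonadherent=nonadherent,
        latent_shift={p: float(latent_z[p]) for p in pids},
    )

    plasma, planted_p, _ = _simulate_matrix(
        "plasma", spec, participants, latent_z, nonadherent, r_plasma
    )
    urine, planted_u, urine_dil = _simulate_matrix(
        "urine", spec, participants, latent_z, nonadherent, r_urine
    )
    truth.planted.update(planted_p)
    truth.planted.update(planted_u)

    _couple_cross_fluid(plasma, urine, urine_dil, truth, spec, r_cross)

    if spec.drift_per_injection != 0.0:
        plasma = apply_drift(plasma, truth, spec.drift_per_injection)
        urine = apply_drift(urine, truth, spec.drift_per_injection)
    if spec.lod_quantile > 0.0:
        plasma = censor_lod(plasma, spec.lod_quantile, truth)
        urine = censor_lod(urine, spec.lod_quantile, truth)

    nutrients = _make_nutrients(spec, participants, latent_z, r_nutr)
    plasma.validate()
    urine.validate()
    return plasma, urine, nutrients, truth


def global_injection_index(table: FeatureTable) -> pd.Series:
    """0-based global injection index from run order and within-run position."""
    meta = table.samples.loc[table.sample_ids]
    if meta["injection_position"].isna().any():
        raise ValidationError("injection positions must be set to model drift")
    runs = sorted(meta["run_id"].dropna().unique())
    run_rank = {r: i for i, r in enumerate(runs)}
    per_run = meta.groupby("run_id")["injection_position"].max().max()
    idx = meta["run_id"].map(run_rank) * int(per_run) + (meta["injection_position"] - 1)
    return idx.astype(int)


def apply_drift(
    table: FeatureTable, truth: GroundTruth, drift_per_injection: float
) -> FeatureTable:
    """Multiply responses by ``(1 + drift)^(global injection index)``.

    Models analyte-specific ESI response drift over the acquisition
    sequence; internal-standard and creatinine features are exempt (their
    responses track the spiked/abundant reference the drift is relative
    to), so drift survives normalization and must be handled by batch
    correction. Factors are recorded in the ground truth.
    """
    out = table.copy()
    idx = global_injection_index(table)
    factors = (1.0 + drift_per_injection) ** idx.to_numpy(float)
    fseries = pd.Series(factors, index=table.sample_ids)
    if "role" in table.features.columns:
        affected = (table.features["role"] == "metabolite").to_numpy()
    else:
        affected = np.ones(table.n_features, dtype=bool)
    vals = out.responses.to_numpy()
    vals[affected, :] = vals[affected, :] * factors[None, :]
    out.responses = pd.DataFrame(vals, index=table.feature_ids, columns=table.sample_ids)
    matrix = _table_matrix(table)
    truth.drift_factors[matrix] = fseries
    return out


def censor_lod(
    table: FeatureTable, lod_quantile: float, truth: GroundTruth
) -> FeatureTable:
    """Censor, per feature, responses below the empirical ``lod_quantile``.

    With n samples, exactly ``floor(lod_quantile * n)`` values per feature
    fall below the threshold (the next order statistic) and become missing.
    Internal-standard and creatinine features are exempt: the downstream
    normalizations require them present in every sample.
    """
    if not (0.0 <= lod_quantile < 1.0):
        raise ValidationError(f"lod_quantile={lod_quantile} must be in [0, 1)")
    out = table.copy()
    n = table.n_samples
    k = int(np.floor(lod_quantile * n))
    if k == 0:
        return out
    roles = (
        table.features["role"]
        if "role" in table.features.columns
        else pd.Series("metabolite", index=table.feature_ids)
    )
    vals = out.responses.to_numpy()
    for i, fid in enumerate(table.feature_ids):
        if roles.loc[fid] != "metabolite":
            continue
        row = vals[i]
        finite = row[~np.isnan(row)]
        if len(finite) <= k:
            continue
        thr = float(np.partition(finite, k)[k])
        row[row < thr] = np.nan
        truth.lod[fid] = thr
    out.responses = pd.DataFrame(vals, index=table.feature_ids, columns=table.sample_ids)
    return out


def _table_matrix(table: FeatureTable) -> str:
    m = table.samples["matrix"].dropna().unique()
    return str(m[0]) if len(m) else "unknown"
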