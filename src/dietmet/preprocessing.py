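"""Data-reduction workflow: normalization, QC filters, imputation,
QC-anchored batch correction, variance-stabilizing transforms, paired ratios.

The default stage order for a matrix is: internal-standard normalization ->
(urine only) creatinine normalization -> detection filter -> QC-CV filter ->
half-minimum imputation -> (urine only) batch correction -> glog ->
autoscale. Paired week2/baseline ratios are formed from the imputed,
batch-corrected, untransformed responses and then glog+autoscaled for the
multivariate models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureTable, ValidationError

log = logging.getLogger("dietmet")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _ratio_normalize(table: FeatureTable, ref_feature: str, what: str) -> FeatureTable:
    if ref_feature not in table.feature_ids:
        raise ValidationError(f"{what} feature {ref_feature!r} not in table")
    ref = table.responses.loc[ref_feature]
    bad = ref.index[ref.isna() | (ref <= 0)]
    if len(bad):
        raise ValidationError(
            f"{what} response missing or non-positive in sample {bad[0]!r}"
        )
    out = table.copy()
    out.responses = out.responses.div(ref, axis=1)
    return out


def normalize_internal_standard(table: FeatureTable, is_feature: str) -> FeatureTable:
    """Divide every response by the sample's internal-standard response.

    Removes per-injection efficiency variation. The internal-standard
    feature itself is flagged (``excluded=True``) so downstream statistics
    skip it.
    """
    out = _ratio_normalize(table, is_feature, "internal standard")
    out.features = out.features.copy()
    out.features.loc[is_feature, "excluded"] = True
    return out


def normalize_creatinine(table: FeatureTable, creatinine_feature: str) -> FeatureTable:
    """Divide urine responses by per-sample creatinine, correcting hydration
    status; units become response per unit creatinine."""
    out = _ratio_normalize(table, creatinine_feature, "creatinine")
    out.features = out.features.copy()
    out.features.loc[creatinine_feature, "excluded"] = True
    return out


def excluded_mask(table: FeatureTable) -> np.ndarray:
    """Features flagged as excluded (normalization references, constants)."""
    if "excluded" not in table.features.columns:
        return np.zeros(table.n_features, dtype=bool)
    col = table.features.loc[table.feature_ids, "excluded"]
    return (col == True).to_numpy()  # noqa: E712  (NaN-safe truth test)


# ---------------------------------------------------------------------------
# QC summary and filters
# ---------------------------------------------------------------------------

@dataclass
class QcSummary:
    """Per-feature detection fraction, QC CV, and retention verdict."""

    table: pd.DataFrame  # columns: detection_fraction, qc_cv, retained, reason

    def retained_ids(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    @staticmethod
    def merge(a: "QcSummary", b: "QcSummary") -> "QcSummary":
        merged = a.table.copy()
        common = merged.index.intersection(b.table.index)
        merged.loc[common, "qc_cv"] = b.table.loc[common, "qc_cv"]
        drop_b = b.table.index[~b.table["retained"]]
        merged.loc[merged.index.intersection(drop_b), "retained"] = False
        for fid in merged.index.intersection(drop_b):
            if merged.loc[fid, "reason"] == "ok":
                merged.loc[fid, "reason"] = b.table.loc[fid, "reason"]
        return QcSummary(merged)


def detection_fractions(table: FeatureTable) -> pd.Series:
    """Fraction of non-QC samples in which each feature is non-missing."""
    study = table.responses.loc[:, table.study_ids()]
    if study.shape[1] == 0:
        raise ValidationError("no study (non-QC) samples present")
    return study.notna().sum(axis=1) / study.shape[1]


def qc_cvs(table: FeatureTable) -> pd.Series:
    """Per-feature CV (sample SD / mean, ddof=1) over non-missing QC responses.

    NaN where fewer than 2 QC observations exist.
    """
    qc = table.responses.loc[:, table.qc_ids()]
    n = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = sd / mean
    cv[n < 2] = np.nan
    return cv


def filter_detection(
    table: FeatureTable, min_fraction: float
) -> tuple[FeatureTable, QcSummary]:
    """Drop features detected in fewer than ``min_fraction`` of study samples.

    The comparison is ``fraction >= min_fraction`` (a feature exactly at the
    threshold is retained). Flagged reference features are kept regardless.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValidationError(f"min_fraction={min_fraction} outside (0, 1]")
    frac = detection_fractions(table)
    keep = (frac >= min_fraction) | excluded_mask(table)
    summary = pd.DataFrame({
        "detection_fraction": frac,
        "qc_cv": np.nan,
        "retained": keep,
        "reason": np.where(keep, "ok", "low-detection"),
    })
    kept = table.with_responses(table.responses.loc[keep])
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("detection filter: removed %d/%d features", n_drop, table.n_features)
    return kept, QcSummary(summary)


def filter_qc_cv(table: FeatureTable, max_cv: float) -> tuple[FeatureTable, QcSummary]:
    """Drop features with QC CV >= ``max_cv`` (strict ``< max_cv`` retains).

    Features with fewer than 2 QC observations have undefined CV and are
    retained with a warning.
    """
    if max_cv <= 0:
        raise ValidationError(f"max_cv={max_cv} must be positive")
    cv = qc_cvs(table)
    undefined = cv.isna()
    if undefined.any():
        log.warning(
            "QC CV undefined for %d feature(s) (<2 QC observations); retained",
            int(undefined.sum()),
        )
    keep = (cv < max_cv) | undefined | excluded_mask(table)
    summary = pd.DataFrame({
        "detection_fraction": np.nan,
        "qc_cv": cv,
        "retained": keep,
        "reason": np.where(keep, np.where(undefined, "cv-undefined", "ok"), "high-cv"),
    })
    kept = table.with_responses(table.responses.loc[keep])
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("QC-CV filter: removed %d/%d features", n_drop, table.n_features)
    return kept, QcSummary(summary)


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace each feature's missing values by half its minimum observed
    response; non-missing cells are untouched."""
    out = table.copy()
    vals = out.responses.to_numpy()
    for i, fid in enumerate(table.feature_ids):
        row = vals[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        observed = row[~miss]
        if len(observed) == 0 or np.nanmin(observed) <= 0:
            raise ValidationError(
                f"feature {fid!r} has no positive observed response to impute from"
            )
        row[miss] = observed.min() / 2.0
    out.responses = pd.DataFrame(vals, index=table.feature_ids, columns=table.sample_ids)
    return out


# ---------------------------------------------------------------------------
# Batch correction
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Per-(batch, feature) location shifts on the natural-log scale.

    ``shifts`` holds the posterior batch deviations from the cross-batch
    prior mean; applying the model subtracts them, ``invert`` adds them
    back. Hyperparameters are the per-feature prior mean and the
    method-of-moments (sigma2, tau2) estimates used for shrinkage.
    """

    anchoring: str
    shifts: pd.DataFrame            # batches x features, log-scale
    prior_mean: pd.Series           # per feature
    sigma2: pd.Series               # within-batch anchor variance per feature
    tau2: pd.Series                 # across-batch variance per feature
    batch_of: pd.Series = field(repr=False, default=None)  # sample -> batch

    def apply(self, table: FeatureTable, inverse: bool = False) -> FeatureTable:
        out = table.copy()
        logx = np.log(out.responses.to_numpy())
        sign = 1.0 if inverse else -1.0
        cols = out.sample_ids
        present = set(out.feature_ids)
        common = [f for f in self.shifts.columns if f in present]
        shift_mat = self.shifts.loc[self.batch_of.loc[cols], common].to_numpy().T
        rows = [out.feature_ids.get_loc(f) for f in common]
        logx[rows, :] += sign * shift_mat
        out.responses = pd.DataFrame(
            np.exp(logx), index=out.feature_ids, columns=cols
        )
        return out

    def invert(self, table: FeatureTable) -> FeatureTable:
        return self.apply(table, inverse=True)


def batch_correct(
    table: FeatureTable,
    anchoring: str = "qc",
    shrink: bool = True,
) -> tuple[FeatureTable, BatchModel]:
    """QC-anchored location correction on the log scale, batch = run.

    Per feature, each batch's anchor mean (QC samples in ``qc`` mode, all
    samples in ``grand-mean`` mode) is shrunk toward the cross-batch prior
    mean by precision weighting::

        posterior = (n/sigma2 * batch_mean + 1/tau2 * prior) / (n/sigma2 + 1/tau2)

    with ``sigma2`` the pooled within-batch anchor variance and ``tau2`` a
    method-of-moments estimate of the across-batch variance. With a single
    anchor per batch (the default serial-injection design) the within-batch
    variance is not estimable and the posterior is the batch mean itself;
    ``shrink=False`` forces that limit (tau2 -> infinity). The correction
    subtracts the posterior deviation from the prior, so a pure location
    shift between batches is removed exactly when shrinkage is off.

    Requires strictly positive, non-missing responses (impute first).
    """
    if anchoring not in ("qc", "grand-mean"):
        raise ValidationError(f"unknown anchoring mode {anchoring!r}")
    resp = table.responses
    if resp.isna().any().any() or (resp <= 0).any().any():
        raise ValidationError("batch correction requires positive, imputed responses")
    meta = table.samples.loc[table.sample_ids]
    if meta["run_id"].isna().any():
        raise ValidationError("run_id must be set on every sample")
    batch_of = meta["run_id"]
    batches = sorted(batch_of.unique())

    qc = table.qc_mask()
    if anchoring == "qc":
        anchors = pd.Series(qc, index=table.sample_ids)
        for b in batches:
            in_b = batch_of == b
            if not (anchors & in_b).any():
                raise ValidationError(f"run {b!r} has no QC sample for qc anchoring")
    else:
        anchors = pd.Series(True, index=table.sample_ids)

    logx = pd.DataFrame(
        np.log(resp.to_numpy()), index=table.feature_ids, columns=table.sample_ids
    )
    anchor_cols = logx.loc[:, anchors[anchors].index]
    grp = anchor_cols.T.groupby(batch_of.loc[anchor_cols.columns])
    batch_mean = grp.mean()                     # batches x features
    batch_n = grp.size()
    batch_var = grp.var(ddof=1)

    prior = batch_mean.mean(axis=0)             # per feature
    between = batch_mean.var(axis=0, ddof=1) if len(batches) > 1 else pd.Series(
        0.0, index=logx.index
    )

    pooled_var = batch_var.mul(batch_n - 1, axis=0).sum(axis=0)
    pooled_df = float((batch_n - 1).sum())
    if shrink and pooled_df > 0:
        sigma2 = (pooled_var / pooled_df).clip(lower=1e-12)
        mean_inv_n = float((1.0 / batch_n).mean())
        tau2 = (between - sigma2 * mean_inv_n).clip(lower=1e-12)
        prec_batch = batch_n.to_numpy()[:, None] / sigma2.to_numpy()[None, :]
        prec_prior = 1.0 / tau2.to_numpy()[None, :]
        post = (
            prec_batch * batch_mean.to_numpy() + prec_prior * prior.to_numpy()[None, :]
        ) / (prec_batch + prec_prior)
        posterior = pd.DataFrame(post, index=batch_mean.index, columns=batch_mean.columns)
    else:
        # single anchor per batch (or shrinkage disabled): posterior = batch mean
        sigma2 = pd.Series(0.0, index=logx.index)
        tau2 = between
        posterior = batch_mean

    shifts = posterior.sub(prior, axis=1)
    if len(batches) == 1:
        shifts.loc[:, :] = 0.0
    model = BatchModel(
        anchoring=anchoring, shifts=shifts, prior_mean=prior,
        sigma2=sigma2, tau2=tau2, batch_of=batch_of,
    )
    return model.apply(table), model


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def glog_transform(table: FeatureTable, lam: float | str = "auto") -> FeatureTable:
    """Generalized log: x -> log2((x + sqrt(x^2 + lambda^2)) / 2).

    ``lam="auto"`` uses the smallest positive non-missing response in the
    table; ``lam=0`` reduces to plain log2. Strictly monotone for any
    lambda >= 0; variance-stabilizing for intensities near zero.
    """
    if lam == "auto":
        vals = table.responses.to_numpy()
        pos = vals[np.isfinite(vals) & (vals > 0)]
        if len(pos) == 0:
            raise ValidationError("no positive responses to set glog lambda from")
        lam = float(pos.min())
    if not isinstance(lam, (int, float)) or lam < 0:
        raise ValidationError(f"glog lambda={lam!r} must be >= 0")
    out = table.copy()
    x = out.responses.to_numpy()
    with np.errstate(divide="ignore"):  # x=0 at lambda=0 -> -inf, the log2 limit
        vals = np.log2((x + np.sqrt(x * x + float(lam) ** 2)) / 2.0)
    out.responses = pd.DataFrame(vals, index=table.feature_ids, columns=table.sample_ids)
    return out


def autoscale(table: FeatureTable) -> FeatureTable:
    """Per-feature mean-centering and unit-variance (ddof=1) scaling.

    Zero-variance features are flagged ``excluded`` (left centered at zero)
    so multivariate models skip them.
    """
    out = table.copy()
    x = out.responses
    if x.shape[1] < 2:
        raise ValidationError("autoscaling needs >= 2 samples")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd <= 0
    scaled = x.sub(mean, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    out.responses = scaled
    if degenerate.any():
        out.features = out.features.copy()
        out.features.loc[degenerate[degenerate].index, "excluded"] = True
        log.warning("autoscale: %d constant feature(s) flagged", int(degenerate.sum()))
    return out


def paired_ratios(table: FeatureTable) -> FeatureTable:
    """Per-participant week2/baseline response ratios.

    Output columns are participants; participants missing a timepoint are
    dropped with a warning. Requires positive baseline responses (impute
    first).
    """
    meta = table.samples.loc[table.study_ids()]
    by_p: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        by_p.setdefault(row["participant_id"], {})[row["timepoint"]] = sid
    cols, data, kept_meta = [], [], []
    dropped = 0
    for pid, tps in by_p.items():
        if "baseline" not in tps or "week2" not in tps:
            dropped += 1
            continue
        base = table.responses[tps["baseline"]]
        wk2 = table.responses[tps["week2"]]
        if (base <= 0).any() or base.isna().any() or wk2.isna().any():
            bad = base.index[(base <= 0) | base.isna()][:1]
            raise ValidationError(
                f"cannot form ratio for participant {pid!r}: baseline response "
                f"non-positive or missing (e.g. feature {list(bad)})"
            )
        cols.append(pid)
        data.append((wk2 / base).to_numpy())
        srow = meta.loc[tps["week2"]]
        kept_meta.append((pid, srow["arm"], srow["age"], srow["sex"], srow["bmi"]))
    if dropped:
        log.warning("paired_ratios: dropped %d participant(s) missing a timepoint", dropped)
    resp = pd.DataFrame(np.array(data).T, index=table.feature_ids, columns=cols)
    samples = pd.DataFrame(
        kept_meta, columns=["participant_id", "arm", "age", "sex", "bmi"]
    ).set_index(pd.Index(cols, name="sample_id"))
    samples["participant_id"] = cols
    return FeatureTable(resp, table.features.copy(), samples, kind="ratios")


# ---------------------------------------------------------------------------
# Matrix-level convenience pipeline
# ---------------------------------------------------------------------------

def find_feature_by_role(table: FeatureTable, role: str) -> str | None:
    if "role" not in table.features.columns:
        return None
    hits = table.features.index[table.features["role"] == role]
    return str(hits[0]) if len(hits) else None


def preprocess_matrix(
    table: FeatureTable,
    *,
    matrix: str,
    detection_fraction_min: float = 0.75,
    qc_cv_max: float = 0.30,
    glog_lambda: float | str = "auto",
    batch_correct_urine: bool = True,
    is_feature: str | None = None,
    creatinine_feature: str | None = None,
) -> dict:
    """Run the full per-matrix workflow; returns a dict of stage outputs.

    Keys: ``normalized`` (post-normalization), ``filtered`` (post filters),
    ``imputed``, ``corrected`` (post batch correction; equals imputed for
    plasma), ``glog``, ``scaled``, ``ratios`` (untransformed paired ratios),
    ``ratios_scaled`` (glog+autoscaled ratios), ``qc`` (QcSummary),
    ``batch_model`` (or None), ``counts`` (telescoping feature counts).
    """
    counts = {"input": table.n_features}
    is_feature = is_feature or find_feature_by_role(table, "internal_standard")
    if is_feature is not None:
        table = normalize_internal_standard(table, is_feature)
    if matrix == "urine":
        creatinine_feature = creatinine_feature or find_feature_by_role(table, "creatinine")
        if creatinine_feature is not None:
            table = normalize_creatinine(table, creatinine_feature)
    normalized = table

    filtered, qc1 = filter_detection(normalized, detection_fraction_min)
    counts["after_detection"] = filtered.n_features
    filtered, qc2 = filter_qc_cv(filtered, qc_cv_max)
    counts["after_qc_cv"] = filtered.n_features
    qc = QcSummary.merge(qc1, qc2)

    # drop the reference features from the analysis matrix
    keep = ~excluded_mask(filtered)
    analysis = filtered.with_responses(filtered.responses.loc[keep])
    counts["analysis"] = analysis.n_features

    imputed = impute_half_min(analysis)
    batch_model = None
    corrected = imputed
    if matrix == "urine" and batch_correct_urine:
        corrected, batch_model = batch_correct(imputed, anchoring="qc")
    glogged = glog_transform(corrected, glog_lambda)
    scaled = autoscale(glogged)

    study = corrected.with_responses(corrected.responses.loc[:, corrected.study_ids()])
    ratios = paired_ratios(study)
    ratios_scaled = autoscale(glog_transform(ratios, glog_lambda))
    return {
        "normalized": normalized, "filtered": filtered, "imputed": imputed,
        "corrected": corrected, "glog": glogged, "scaled": scaled,
        "ratios": ratios, "ratios_scaled": ratios_scaled,
        "qc": qc, "batch_model": batch_model, "counts": counts,
    }
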