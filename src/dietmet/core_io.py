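"""Data model, delimited-table I/O, and run configuration.

The pipeline's central object is the :class:`FeatureTable`: a features x
samples matrix of non-negative peak responses together with feature metadata
(m/z, relative migration time, ion mode, platform, identification level) and
sample metadata (participant, treatment arm, timepoint, biofluid matrix,
covariates, run/injection position, QC flag).

Missing responses are a first-class concept: on disk they are empty cells,
in memory they are NaN. A measured zero is a legal value distinct from
missing; readers can optionally reinterpret zeros as missing
(``zeros_as_missing``) for data exported under the convention that values
below the detection limit were stored as zero.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("dietmet")

ARMS = ("W-P", "P-W")
TIMEPOINTS = ("baseline", "week2")
MATRICES = ("plasma", "urine")
ION_MODES = ("+", "-")
PLATFORMS = ("MSI-CE-MS", "GC-MS", "CE-UV")

SAMPLE_COLUMNS = [
    "participant_id", "arm", "timepoint", "matrix", "age", "sex", "bmi",
    "run_id", "injection_position", "is_qc",
]
FEATURE_COLUMNS = ["name", "mz", "rmt", "ion_mode", "platform", "id_level"]

#: float format used for all on-disk numbers; round-trips doubles exactly
FLOAT_FORMAT = "%.17g"


class ValidationError(ValueError):
    """A table, config, or argument violates a documented invariant."""


class ParseError(ValueError):
    """A delimited input file is structurally inconsistent."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Features x samples response matrix plus metadata sidecars.

    Parameters
    ----------
    responses
        DataFrame indexed by feature_id with sample_id columns. NaN marks a
        missing (below-LOD / not detected) response; all other values must
        be >= 0.
    features
        DataFrame indexed by feature_id. Recognised columns are
        ``name, mz, rmt, ion_mode, platform, id_level``; unknown columns are
        preserved as opaque annotations.
    samples
        DataFrame indexed by sample_id with the ``SAMPLE_COLUMNS`` fields;
        extra columns are preserved.
    kind
        ``"samples"`` for ordinary tables (full design invariants enforced)
        or ``"ratios"`` for paired week2/baseline ratio tables whose columns
        are participants rather than injections.
    """

    responses: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    kind: str = "samples"

    # -- construction helpers ------------------------------------------------

    def __post_init__(self) -> None:
        self.responses = self.responses.astype(float)

    @property
    def n_features(self) -> int:
        return self.responses.shape[0]

    @property
    def n_samples(self) -> int:
        return self.responses.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.responses.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.responses.columns

    def qc_mask(self) -> np.ndarray:
        """Boolean mask over columns: True for pooled-QC injections."""
        if "is_qc" not in self.samples.columns:
            return np.zeros(self.n_samples, dtype=bool)
        col = self.samples.loc[self.sample_ids, "is_qc"]
        return (col == True).to_numpy()  # noqa: E712  (NaN-safe truth test)

    def study_ids(self) -> pd.Index:
        return self.sample_ids[~self.qc_mask()]

    def qc_ids(self) -> pd.Index:
        return self.sample_ids[self.qc_mask()]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.responses.copy(), self.features.copy(), self.samples.copy(), self.kind
        )

    def with_responses(self, responses: pd.DataFrame) -> "FeatureTable":
        """New table sharing metadata, restricted to ``responses``' index/columns."""
        feats = self.features.loc[responses.index]
        samps = self.samples.loc[responses.columns]
        return FeatureTable(responses, feats, samps, self.kind)

    def equals(self, other: "FeatureTable", rtol: float = 1e-12) -> bool:
        if list(self.feature_ids) != list(other.feature_ids):
            return False
        if list(self.sample_ids) != list(other.sample_ids):
            return False
        a, b = self.responses.to_numpy(), other.responses.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True)
        return bool(np.all(close | both_nan))

    # -- validation ----------------------------------------------------------

    def validate(self) -> "FeatureTable":
        resp, feats, samps = self.responses, self.features, self.samples
        if resp.index.has_duplicates:
            dup = resp.index[resp.index.duplicated()][0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        if resp.columns.has_duplicates:
            dup = resp.columns[resp.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        missing_feat = resp.index.difference(feats.index)
        if len(missing_feat):
            raise ValidationError(
                f"feature(s) absent from feature metadata: {list(missing_feat[:5])}"
            )
        missing_samp = resp.columns.difference(samps.index)
        if len(missing_samp):
            raise ValidationError(
                f"sample(s) absent from sample metadata: {list(missing_samp[:5])}"
            )
        extra_samp = samps.index.difference(resp.columns)
        if len(extra_samp):
            raise ValidationError(
                f"sample metadata lists sample(s) absent from the response matrix: "
                f"{list(extra_samp[:5])}"
            )
        vals = resp.to_numpy()
        neg = np.nan_to_num(vals, nan=0.0) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative response for feature {resp.index[i]!r} in sample "
                f"{resp.columns[j]!r}"
            )
        if self.kind == "samples":
            self._validate_design()
        if "id_level" in feats.columns:
            lv = pd.to_numeric(feats["id_level"], errors="coerce").dropna()
            if not lv.isin([1, 2, 3, 4]).all():
                raise ValidationError("id_level must be in {1,2,3,4}")
        return self

    def _validate_design(self) -> None:
        samps = self.samples.loc[self.sample_ids]
        if "is_qc" not in samps.columns:
            return
        qc = samps["is_qc"].fillna(False).astype(bool)
        study = samps.loc[~qc]
        for col in ("arm", "timepoint"):
            if col in study.columns and study[col].isna().any():
                bad = study.index[study[col].isna()][0]
                raise ValidationError(f"non-QC sample {bad!r} has no {col}")
        if "arm" in study.columns:
            bad = set(study["arm"].dropna()) - set(ARMS)
            if bad:
                raise ValidationError(f"unknown arm value(s): {sorted(bad)}")
        if "timepoint" in study.columns:
            bad = set(study["timepoint"].dropna()) - set(TIMEPOINTS)
            if bad:
                raise ValidationError(f"unknown timepoint value(s): {sorted(bad)}")
        qc_rows = samps.loc[qc]
        if "participant_id" in qc_rows.columns and qc_rows["participant_id"].notna().any():
            bad = qc_rows.index[qc_rows["participant_id"].notna()][0]
            raise ValidationError(f"QC sample {bad!r} must not carry a participant_id")
        if {"participant_id", "timepoint", "matrix"} <= set(study.columns):
            dup = study.duplicated(subset=["participant_id", "timepoint", "matrix"])
            if dup.any():
                bad = study.loc[dup].iloc[0]
                raise ValidationError(
                    "participant appears more than once per (timepoint, matrix): "
                    f"{bad['participant_id']!r} at {bad['timepoint']}/{bad['matrix']}"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return Path(f"{base}.samples.csv"), Path(f"{base}.features.csv")


def read_feature_table(
    path: str | Path,
    samples_path: str | Path | None = None,
    features_path: str | Path | None = None,
    *,
    zeros_as_missing: bool = False,
    kind: str = "samples",
) -> FeatureTable:
    """Read a CSV response matrix (rows = features, columns = samples) with
    its sample/feature metadata sidecars and return a validated table.

    Empty cells become NaN (missing). With ``zeros_as_missing=True``, zero
    responses are also converted to missing, reproducing the convention of
    instruments that export below-detection-limit values as zero.
    """
    path = Path(path)
    default_s, default_f = _sidecar_paths(path)
    samples_path = Path(samples_path) if samples_path else default_s
    features_path = Path(features_path) if features_path else default_f

    resp = pd.read_csv(path, index_col=0)
    resp.index = resp.index.astype(str)
    resp.columns = resp.columns.astype(str)
    try:
        resp = resp.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric response cell in {path}: {exc}") from exc

    samples = pd.read_csv(samples_path, index_col=0)
    samples.index = samples.index.astype(str)
    if "is_qc" in samples.columns:
        samples["is_qc"] = samples["is_qc"].astype(bool)
    if features_path.exists():
        features = pd.read_csv(features_path, index_col=0)
        features.index = features.index.astype(str)
    else:
        features = pd.DataFrame(index=resp.index)

    if zeros_as_missing:
        resp = resp.mask(resp == 0.0)

    table = FeatureTable(resp, features, samples, kind=kind)
    table.validate()
    log.info(
        "read feature table %s: %d features x %d samples",
        path.name, table.n_features, table.n_samples,
    )
    return table


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    samples_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> None:
    """Write a table as three CSVs (responses + sample/feature sidecars).

    Numbers use a fixed ``%.17g`` format so write -> read -> write is
    byte-stable and values survive the round trip exactly; missing values
    are written as empty cells.
    """
    path = Path(path)
    default_s, default_f = _sidecar_paths(path)
    samples_path = Path(samples_path) if samples_path else default_s
    features_path = Path(features_path) if features_path else default_f
    table.responses.to_csv(path, float_format=FLOAT_FORMAT, na_rep="")
    table.samples.loc[table.sample_ids].to_csv(samples_path, float_format=FLOAT_FORMAT)
    table.features.loc[table.feature_ids].to_csv(features_path, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and knobs shared by all pipeline stages.

    Defaults encode the study's published working points: detection in
    >=75% of study samples, QC CV < 30%, fold-change cut-off 1.3, alpha and
    FDR q at 0.05, nutrient-correlation floor |r| > 0.30 for >=2 nutrient
    categories, >=2 of 3 models for a robust call, and 1000 label
    permutations for OPLS-DA validation.
    """

    detection_fraction_min: float = 0.75
    qc_cv_max: float = 0.30
    glog_lambda: float | str = "auto"
    fc_min: float = 1.3
    alpha: float = 0.05
    q_threshold: float = 0.05
    r_min: float = 0.30
    n_nutrient_min: int = 2
    n_models_min: int = 2
    n_permutations: int = 1000
    n_orth_components: int = 1
    cv_folds: int = 7
    meba_prior_df: float = 3.0
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        def _in(name: str, lo: float, hi: float, lo_open: bool = False, hi_open: bool = False) -> None:
            v = getattr(self, name)
            ok = (v > lo if lo_open else v >= lo) and (v < hi if hi_open else v <= hi)
            if not ok:
                raise ValidationError(f"{name}={v!r} outside its domain")

        _in("detection_fraction_min", 0.0, 1.0, lo_open=True)
        _in("qc_cv_max", 0.0, np.inf, lo_open=True)
        _in("alpha", 0.0, 1.0, lo_open=True, hi_open=True)
        _in("q_threshold", 0.0, 1.0, lo_open=True, hi_open=True)
        _in("r_min", 0.0, 1.0, hi_open=True)
        if self.fc_min < 1.0:
            raise ValidationError(f"fc_min={self.fc_min} must be >= 1")
        if self.glog_lambda != "auto":
            if not isinstance(self.glog_lambda, (int, float)) or self.glog_lambda < 0:
                raise ValidationError(f"glog_lambda={self.glog_lambda!r} must be 'auto' or >= 0")
        for name in ("n_nutrient_min", "n_models_min", "n_permutations",
                     "cv_folds"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.n_orth_components < 0:
            raise ValidationError("n_orth_components must be >= 0")
        if self.meba_prior_df < 0:
            raise ValidationError("meba_prior_df must be >= 0")
        return self


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML key-value config; unspecified keys take the defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw) if raw.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParseError(f"config {path} is not a key-value mapping")
        data = loaded
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    return cfg.validate()


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)
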