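"""Statistical battery for paired two-arm metabolomics designs.

Implements the complementary models used to rank diet-responsive features:

* volcano analysis (between-arm fold change of paired ratios + t-test,
  Benjamini-Hochberg FDR),
* paired OPLS-DA with stratified cross-validated Q2 and label-permutation
  validation, plus S-plot coordinates,
* a moderated two-group Hotelling T2 statistic for (baseline, week2)
  time profiles, with empirical-Bayes covariance shrinkage,
* the diet x time interaction of the 2-timepoint repeated-measures model,
  computed exactly via the within-subject difference-score regression,
* covariate-adjusted partial Pearson correlation with listwise deletion,
* ROC/AUC by the Mann-Whitney identity for single or ratiometric markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureTable, ValidationError
from .preprocessing import glog_transform


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Volcano
# ---------------------------------------------------------------------------

def volcano(
    ratios: FeatureTable,
    arms: pd.Series | dict[str, str] | None = None,
    fc_min: float = 1.3,
    alpha: float = 0.05,
    glog_lambda: float | str = "auto",
) -> pd.DataFrame:
    """Between-arm analysis of paired week2/baseline ratios.

    ``fc`` is the ratio of geometric-mean ratios (W-P over P-W); ``p`` is a
    pooled-variance two-sample t-test on glog-transformed ratios; ``q`` is
    BH-adjusted within the table. ``significant`` requires both the fold
    change outside [1/fc_min, fc_min] and p < alpha.
    """
    if arms is None:
        arms = ratios.samples.loc[ratios.sample_ids, "arm"]
    arms = pd.Series(arms).loc[ratios.sample_ids]
    g1 = ratios.sample_ids[arms == "W-P"]
    g2 = ratios.sample_ids[arms == "P-W"]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each arm needs >= 2 participants")
    vals = ratios.responses
    if (vals <= 0).any().any() or vals.isna().any().any():
        raise ValidationError("ratios must be positive and complete")
    log_wp = np.log(vals[g1]).mean(axis=1)
    log_pw = np.log(vals[g2]).mean(axis=1)
    fc = np.exp(log_wp - log_pw)

    gl = glog_transform(ratios, glog_lambda).responses
    t, p = stats.ttest_ind(gl[g1], gl[g2], axis=1, equal_var=True)
    q = bh_adjust(np.nan_to_num(p, nan=1.0))
    out = pd.DataFrame({
        "fc": fc, "t": t, "p": p, "q": q,
    }, index=ratios.feature_ids)
    out["significant"] = ((out["fc"] >= fc_min) | (out["fc"] <= 1.0 / fc_min)) & (
        out["p"] < alpha
    )
    return out


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Fitted orthogonal PLS-DA with validation statistics."""

    scores: np.ndarray            # predictive scores t, one per sample
    loadings: np.ndarray          # predictive loadings, one per feature
    r2y: float
    q2: float
    perm_p: float
    perm_q2: np.ndarray = field(repr=False, default=None)
    splot: pd.DataFrame = field(repr=False, default=None)  # cov/corr vs t
    n_orth: int = 1


class _OscPls:
    """One predictive PLS component after n_orth orthogonal-signal-correction
    deflations (single-response O-PLS; the single-y NIPALS solution is
    closed-form, no iteration required)."""

    def __init__(self, n_orth: int):
        self.n_orth = n_orth
        self.w_orth: list[np.ndarray] = []
        self.p_orth: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OscPls":
        Xc = X.copy()
        for _ in range(self.n_orth):
            w = Xc.T @ y
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                raise ValidationError("degenerate X'y; cannot extract component")
            w /= nw
            t = Xc @ w
            p = Xc.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-10:
                raise ValidationError(
                    "no orthogonal variation left (n_orth exceeds the rank of X)"
                )
            w_o /= n_o
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            self.w_orth.append(w_o)
            self.p_orth.append(p_o)
        w = Xc.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValidationError("degenerate X'y; cannot extract component")
        self.w = w / nw
        self.t = Xc @ self.w
        self.p = Xc.T @ self.t / (self.t @ self.t)
        self.c = float(y @ self.t / (self.t @ self.t))
        self.X_filtered = Xc
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = X.copy()
        for w_o, p_o in zip(self.w_orth, self.p_orth):
            t_o = Xc @ w_o
            Xc = Xc - np.outer(t_o, p_o)
        return Xc @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) * self.c


def _q2(
    X: np.ndarray, y: np.ndarray, n_orth: int, folds: np.ndarray
) -> float:
    """Cross-validated Q2: 1 - PRESS/SS over held-out folds."""
    press = 0.0
    for k in np.unique(folds):
        test = folds == k
        model = _OscPls(n_orth).fit(X[~test], y[~test])
        press += float(np.sum((y[test] - model.predict(X[test])) ** 2))
    ss = float(np.sum(y * y))
    return 1.0 - press / ss


def oplsda_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_orth: int = 1,
    cv_folds: int = 7,
    n_perm: int = 1000,
    seed: int = 0,
) -> OplsdaModel:
    """Fit OPLS-DA on an autoscaled matrix (samples x features) with a
    two-class label vector, and validate it.

    Q2 comes from stratified ``cv_folds``-fold cross-validation; the
    permutation p-value is ``(1 + #{permuted Q2 >= observed Q2}) /
    (n_perm + 1)`` with class labels permuted under ``seed`` (Q2, not R2,
    is permuted: cross-validated predictivity is the robustness claim).
    """
    feature_index = X.columns if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y_raw = np.asarray(y)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
    if min((y_raw == c).sum() for c in classes) < 2:
        raise ValidationError("each class needs >= 2 samples")
    y_num = np.where(y_raw == classes[0], 1.0, -1.0)
    y_num = y_num - y_num.mean()

    model = _OscPls(n_orth).fit(X, y_num)
    yhat = model.predict(X)
    ss = float(np.sum(y_num * y_num))
    r2y = 1.0 - float(np.sum((y_num - yhat) ** 2)) / ss

    rng = np.random.default_rng(seed)

    def _stratified_folds(labels: np.ndarray) -> np.ndarray:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        folds = np.empty(len(labels), dtype=int)
        for k, (_, test) in enumerate(skf.split(X, labels)):
            folds[test] = k
        return folds

    q2 = _q2(X, y_num, n_orth, _stratified_folds(y_raw))

    # each permutation recomputes the full statistic, fold stratification
    # included, so permuted and observed Q2 are exchangeable under the null
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(y_num))
        try:
            perm_q2[i] = _q2(X, y_num[perm], n_orth, _stratified_folds(y_raw[perm]))
        except ValidationError:
            perm_q2[i] = -np.inf
    perm_p = (1.0 + float(np.sum(perm_q2 >= q2))) / (n_perm + 1.0)

    t = model.t
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    n = len(t)
    cov = xc.T @ tc / (n - 1)
    denom = xc.std(axis=0, ddof=1) * tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / denom, np.nan)
    splot = pd.DataFrame({"covariance": cov, "correlation": corr},
                         index=feature_index)
    return OplsdaModel(
        scores=t, loadings=model.p, r2y=r2y, q2=q2, perm_p=perm_p,
        perm_q2=perm_q2, splot=splot, n_orth=n_orth,
    )


# ---------------------------------------------------------------------------
# Moderated Hotelling T2 (2-timepoint MEBA-style ranking)
# ---------------------------------------------------------------------------

def hotelling_t2_profiles(
    a: np.ndarray, b: np.ndarray, s_tilde: np.ndarray | None = None
) -> float:
    """Two-sample Hotelling T2 for time profiles (rows = subjects).

    With ``s_tilde`` given, uses that covariance instead of the pooled one
    (the moderated variant).
    """
    n1, n2 = a.shape[0], b.shape[0]
    d = a.mean(axis=0) - b.mean(axis=0)
    if s_tilde is None:
        s = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)) / (
            n1 + n2 - 2
        )
    else:
        s = s_tilde
    try:
        sol = np.linalg.solve(s, d)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular profile covariance") from exc
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def meba_t2(
    table: FeatureTable,
    arms: pd.Series | dict[str, str] | None = None,
    prior_df: float = 3.0,
) -> pd.DataFrame:
    """Moderated group-difference Hotelling T2 over (baseline, week2) profiles.

    Per feature, the pooled within-arm profile covariance S is shrunk toward
    a cross-feature prior S0 = diag(median over features of the pooled
    variances): ``S~ = (n_pooled*S + nu*S0) / (n_pooled + nu)`` with
    ``n_pooled = n1 + n2 - 2`` and ``nu = prior_df``. Features are ranked by
    T2 descending (ties broken by feature id). ``p_approx`` maps T2 through
    the classical Hotelling-to-F relation (exact at nu = 0, approximate
    otherwise); participants with an incomplete profile are dropped.
    """
    meta = table.samples.loc[table.study_ids()]
    if arms is None:
        arms_s = meta.groupby("participant_id")["arm"].first()
    else:
        arms_s = pd.Series(arms)
    prof: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        prof.setdefault(row["participant_id"], {})[row["timepoint"]] = sid
    complete = {p: t for p, t in prof.items() if {"baseline", "week2"} <= set(t)}
    if len(complete) < len(prof):
        import logging
        logging.getLogger("dietmet").warning(
            "meba_t2: dropped %d participant(s) with incomplete profiles",
            len(prof) - len(complete),
        )
    pids = sorted(complete)
    base_cols = [complete[p]["baseline"] for p in pids]
    wk2_cols = [complete[p]["week2"] for p in pids]
    arm_vec = arms_s.loc[pids].to_numpy()
    g1 = np.array([a == "W-P" for a in arm_vec])
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("each arm needs >= 2 complete profiles")

    B = table.responses[base_cols].to_numpy()   # features x subjects
    W = table.responses[wk2_cols].to_numpy()
    if np.isnan(B).any() or np.isnan(W).any():
        raise ValidationError("profiles must be complete (impute first)")

    n_feat = table.n_features
    n_pooled = n1 + n2 - 2
    pooled = np.empty((n_feat, 2, 2))
    d = np.empty((n_feat, 2))
    for i in range(n_feat):
        a = np.column_stack([B[i, g1], W[i, g1]])
        b = np.column_stack([B[i, ~g1], W[i, ~g1]])
        d[i] = a.mean(axis=0) - b.mean(axis=0)
        pooled[i] = (
            (n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)
        ) / n_pooled
    s0 = np.diag(np.median(pooled[:, (0, 1), (0, 1)], axis=0))
    nu = float(prior_df)
    t2 = np.empty(n_feat)
    for i in range(n_feat):
        if np.allclose(d[i], 0.0):
            t2[i] = 0.0  # identical mean profiles: zero regardless of S
            continue
        s_tilde = (n_pooled * pooled[i] + nu * s0) / (n_pooled + nu)
        try:
            sol = np.linalg.solve(s_tilde, d[i])
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"singular moderated covariance for feature {table.feature_ids[i]!r}"
            ) from exc
        t2[i] = n1 * n2 / (n1 + n2) * d[i] @ sol

    p_dim = 2
    n_tot = n1 + n2
    f_stat = (n_tot - p_dim - 1) / (p_dim * (n_tot - 2)) * t2
    p_approx = stats.f.sf(f_stat, p_dim, n_tot - p_dim - 1)
    out = pd.DataFrame({
        "t2": t2, "p_approx": p_approx,
        "prior_df": nu,
        "prior_var_baseline": s0[0, 0], "prior_var_week2": s0[1, 1],
    }, index=table.feature_ids)
    tmp = out.assign(_fid=out.index.to_numpy()).sort_values(
        ["t2", "_fid"], ascending=[False, True], kind="mergesort"
    )
    out.loc[tmp.index, "rank"] = np.arange(1, n_feat + 1)
    out["rank"] = out["rank"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Mixed ANOVA (diet x time interaction via difference scores)
# ---------------------------------------------------------------------------

def _design_matrices(
    arm01: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(arm01)
    cols = [np.ones(n), arm01.astype(float)]
    red = [np.ones(n)]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c].to_numpy(dtype=float)
            cols.append(v)
            red.append(v)
    Z = np.column_stack(cols)
    Z0 = np.column_stack(red)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValidationError(
            "collinear design: the arm term or a covariate is redundant "
            f"(columns: intercept, arm, {list(covariates.columns) if covariates is not None else []})"
        )
    return Z, Z0


def mixed_anova_interaction(
    table: FeatureTable,
    arms: pd.Series | dict[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Diet x time interaction F for every feature, adjusted for covariates.

    With two timepoints the repeated-measures interaction is exactly the
    between-arm comparison of within-subject differences, so each feature's
    difference score (week2 - baseline, on the transformed scale) is
    regressed on arm + covariates and the partial F for the arm term
    (df1 = 1) is reported. Covariates are taken from the sample metadata
    (age, sex coded F=0/M=1, bmi) when not supplied.
    """
    meta = table.samples.loc[table.study_ids()]
    prof: dict[str, dict[str, str]] = {}
    for sid, row in meta.iterrows():
        prof.setdefault(row["participant_id"], {})[row["timepoint"]] = sid
    pids = sorted(p for p, t in prof.items() if {"baseline", "week2"} <= set(t))
    base_cols = [prof[p]["baseline"] for p in pids]
    wk2_cols = [prof[p]["week2"] for p in pids]
    delta = (
        table.responses[wk2_cols].to_numpy() - table.responses[base_cols].to_numpy()
    )  # features x subjects
    if arms is None:
        arms_s = meta.groupby("participant_id")["arm"].first()
    else:
        arms_s = pd.Series(arms)
    arm01 = (arms_s.loc[pids] == "W-P").to_numpy(dtype=float)
    if covariates is None and {"age", "sex", "bmi"} <= set(meta.columns):
        cov = meta.groupby("participant_id")[["age", "sex", "bmi"]].first().loc[pids]
        covariates = pd.DataFrame({
            "age": cov["age"].astype(float),
            "sex": (cov["sex"] == "M").astype(float),
            "bmi": cov["bmi"].astype(float),
        }, index=pids)
    elif covariates is not None:
        covariates = covariates.loc[pids]
    return anova_delta(delta.T, arm01, covariates, index=table.feature_ids)


def anova_delta(
    delta: np.ndarray,
    arm01: np.ndarray,
    covariates: pd.DataFrame | None = None,
    index: pd.Index | None = None,
) -> pd.DataFrame:
    """Partial-F for the arm term in delta ~ arm + covariates, vectorized
    over columns of ``delta`` (subjects x features)."""
    Z, Z0 = _design_matrices(arm01, covariates)
    n, p_full = Z.shape
    if n <= p_full:
        raise ValidationError("not enough subjects for the requested covariates")
    Y = np.atleast_2d(np.asarray(delta, dtype=float))
    if Y.shape[0] != n:
        Y = Y.T
    beta_full, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    beta_red, *_ = np.linalg.lstsq(Z0, Y, rcond=None)
    rss_full = np.sum((Y - Z @ beta_full) ** 2, axis=0)
    rss_red = np.sum((Y - Z0 @ beta_red) ** 2, axis=0)
    df2 = n - p_full
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (rss_red - rss_full) / (rss_full / df2)
    f = np.clip(f, 0.0, None)
    p = stats.f.sf(f, 1, df2)
    return pd.DataFrame({"f": f, "p": p, "df1": 1, "df2": df2}, index=index)


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    r: float
    p: float
    n_used: int
    ok: bool = True


def partial_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Rows with any missing entry are dropped (listwise deletion); x and y are
    residualized on the covariates (with intercept) by least squares and the
    Pearson correlation of the residuals is returned with the t-based
    two-sided p at df = n - 2 - k. Zero-variance residuals yield an
    undefined (ok=False) result rather than a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[mask], y[mask], C[mask]
    n, k = len(x), C.shape[1]
    if n < k + 3:
        raise ValidationError(f"need >= {k + 3} complete rows, have {n}")
    Z = np.column_stack([np.ones(n), C])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        return PartialCorrResult(np.nan, np.nan, n, ok=False)
    r = float(rx @ ry / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return PartialCorrResult(r, 0.0, n)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PartialCorrResult(r, float(p), n)


def partial_correlation_matrix(
    X: pd.DataFrame, Y: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs partial correlations between columns of X and of Y.

    Listwise over the full row set; returns (r, p) DataFrames of shape
    (X columns x Y columns). Vectorized equivalent of calling
    :func:`partial_correlation` per pair on complete data.
    """
    idx = X.index
    Xv = X.to_numpy(dtype=float)
    Yv = Y.loc[idx].to_numpy(dtype=float)
    if covariates is None:
        C = np.empty((len(idx), 0))
    else:
        C = covariates.loc[idx].to_numpy(dtype=float)
    mask = (
        np.all(np.isfinite(Xv), axis=1)
        & np.all(np.isfinite(Yv), axis=1)
        & np.all(np.isfinite(C), axis=1)
    )
    Xv, Yv, C = Xv[mask], Yv[mask], C[mask]
    n, k = Xv.shape[0], C.shape[1]
    if n < k + 3:
        raise ValidationError("too few complete rows for partial correlation")
    Z = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(Z)
    RX = Xv - Q @ (Q.T @ Xv)
    RY = Yv - Q @ (Q.T @ Yv)
    RX /= np.linalg.norm(RX, axis=0, keepdims=True)
    RY /= np.linalg.norm(RY, axis=0, keepdims=True)
    r = np.clip(RX.T @ RY, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return (
        pd.DataFrame(r, index=X.columns, columns=Y.columns),
        pd.DataFrame(p, index=X.columns, columns=Y.columns),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    p: float
    threshold: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def roc_auc(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    positive: object | None = None,
) -> RocResult:
    """AUC by the Mann-Whitney identity (ties count 1/2) with the
    normal-approximation Mann-Whitney p-value, and sensitivity/specificity
    at the Youden-optimal threshold (marker >= threshold calls positive)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {list(classes)}")
    if positive is None:
        positive = classes[0]
    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("one class is empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(u.statistic) / (len(pos) * len(neg))

    thresholds = np.unique(values)
    best = (-np.inf, np.inf, 0.0, 0.0)
    for thr in thresholds:
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return RocResult(
        auc=auc, p=float(u.pvalue), threshold=float(best[1]),
        sensitivity=best[2], specificity=best[3],
        n_pos=len(pos), n_neg=len(neg),
    )


def ratio_marker(
    table: FeatureTable, numerator: str, denominator: str
) -> pd.Series:
    """Ratiometric marker from untransformed responses of two features."""
    num = table.responses.loc[numerator]
    den = table.responses.loc[denominator]
    if (den <= 0).any() or den.isna().any():
        raise ValidationError(f"denominator {denominator!r} must be positive everywhere")
    return num / den
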