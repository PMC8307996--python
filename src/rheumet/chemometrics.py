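"""SIMCA-style chemometrics: unit-variance scaling, PCA with the Hotelling
T2 95% ellipse, two-class NIPALS PLS-DA with sevenfold cross-validated Q2,
CV-ANOVA model validation, VIP scores, and the VIP > 1.00 AND q < 0.05
biomarker intersection.

Cross-validation refits the unit-variance scaling inside every training
fold, so Q2 and CV-ANOVA carry no scaling leakage.  CV-ANOVA follows the
Eriksson et al. (2008) convention::

    F = [(SS - PRESS) / A] / [PRESS / (N - A - 1)],  p = F-survival(A, N-A-1)

with A latent variables and N samples; PRESS >= SS reports p = 1 rather
than an error.  A permutation-based p is available as a cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("rheumet.chemometrics")

__all__ = [
    "Scaler", "PCAModel", "PLSDAModel", "EllipseSpec",
    "uv_scale", "randomize_sample_order", "fit_pca", "hotelling_ellipse",
    "fit_plsda", "cross_validated_q2", "cv_anova", "vip_scores",
    "select_discriminant_metabolites", "select_n_lv", "fit_plsda_cv",
    "model_summary", "score_plot",
]


# --------------------------------------------------------------------------
# scaling
# --------------------------------------------------------------------------

@dataclass
class Scaler:
    mean: pd.Series
    sd: pd.Series
    kept: list[str]
    dropped: list[str] = field(default_factory=list)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values[self.kept] - self.mean[self.kept]) / self.sd[self.kept]


def uv_scale(features) -> tuple[pd.DataFrame, Scaler]:
    """Unit-variance (auto)scaling: each retained column to mean 0, sd 1.

    Zero-variance columns are excluded with a warning.
    """
    values = features.values if hasattr(features, "metabolites") \
        else pd.DataFrame(features)
    if len(values) < 2:
        raise ValueError("need >= 2 samples")
    sd = values.std(ddof=1)
    kept = [c for c in values.columns if sd[c] > 0]
    dropped = [c for c in values.columns if sd[c] == 0]
    if not kept:
        raise ValueError("all columns have zero variance")
    if dropped:
        log.warning("dropping zero-variance columns: %s", dropped)
    scaler = Scaler(values.mean(), sd, kept, dropped)
    return scaler.transform(values), scaler


def randomize_sample_order(matrix, meta, seed: int = 0):
    """Jointly permute sample rows of a matrix and its metadata."""
    rng = np.random.default_rng(seed)
    n = len(matrix)
    perm = rng.permutation(n)
    if isinstance(matrix, pd.DataFrame):
        return matrix.iloc[perm], meta.iloc[perm]
    return np.asarray(matrix)[perm], meta.iloc[perm]


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    n_pc: int
    loadings: np.ndarray          # variables x PCs, orthonormal
    scores: np.ndarray            # samples x PCs
    r2x: np.ndarray               # per PC
    r2x_cum: np.ndarray
    mean: np.ndarray
    columns: list[str]


def fit_pca(X, n_pc: int) -> PCAModel:
    """PCA by SVD of the column-centered matrix.

    R2X per PC is the explained fraction of the total (centered) sum of
    squares; with all PCs the reconstruction is exact.
    """
    Xdf = pd.DataFrame(X)
    Xv = Xdf.to_numpy(dtype=float)
    n, k = Xv.shape
    if n_pc > min(n - 1, k):
        raise ValueError("n_pc exceeds min(n_samples - 1, n_variables)")
    mean = Xv.mean(axis=0)
    Xc = Xv - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s ** 2).sum()
    r2x = (s[:n_pc] ** 2) / total
    return PCAModel(n_pc, vt[:n_pc].T, u[:, :n_pc] * s[:n_pc],
                    r2x, np.cumsum(r2x), mean, list(Xdf.columns))


# --------------------------------------------------------------------------
# Hotelling T2 ellipse
# --------------------------------------------------------------------------

@dataclass
class EllipseSpec:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    confidence: float = 0.95

    def contains(self, x, y) -> np.ndarray:
        (cx, cy), (a, b) = self.center, self.semi_axes
        return ((np.asarray(x) - cx) / a) ** 2 \
            + ((np.asarray(y) - cy) / b) ** 2 <= 1.0


def hotelling_ellipse(scores, confidence: float = 0.95) -> EllipseSpec:
    """Hotelling T2 confidence ellipse for the first two score vectors.

    semi_axis_i = s_i * sqrt(2 (n-1)(n+1) / (n (n-2)) * F_{conf; 2, n-2}).
    """
    sc = np.asarray(scores, dtype=float)[:, :2]
    n = sc.shape[0]
    if n < 4:
        raise ValueError("need n >= 4")
    s = sc.std(axis=0, ddof=1)
    fcrit = stats.f.ppf(confidence, 2, n - 2)
    factor = np.sqrt(2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * fcrit)
    if np.any(s == 0):
        raise ValueError("degenerate scores (zero variance)")
    return EllipseSpec((float(sc[:, 0].mean()), float(sc[:, 1].mean())),
                       (float(s[0] * factor), float(s[1] * factor)),
                       confidence)


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_lv: int
    weights: np.ndarray           # K x A
    x_loadings: np.ndarray        # K x A
    x_scores: np.ndarray          # n x A
    y_loadings: np.ndarray        # A
    class_map: dict
    columns: list[str]
    y_mean: float
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray
    q2_cum: float = np.nan
    vip: np.ndarray | None = None
    cv_anova_p: float = np.nan
    cv_config: dict = field(default_factory=dict)

    @property
    def coef(self) -> np.ndarray:
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X) -> np.ndarray:
        Xv = pd.DataFrame(X)[self.columns].to_numpy(dtype=float) \
            if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return Xv @ self.coef + self.y_mean


def encode_classes(y) -> tuple[np.ndarray, dict]:
    labels = sorted(pd.unique(np.asarray(y)))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 classes required, got {labels}")
    cmap = {labels[0]: 0.0, labels[1]: 1.0}
    return np.array([cmap[v] for v in np.asarray(y)]), cmap


def fit_plsda(X, y, n_lv: int = 2, tol: float = 1e-10,
              max_iter: int = 500) -> PLSDAModel:
    """Two-class PLS-DA via NIPALS on a (scaled) matrix.

    ``y`` holds the class labels; it is encoded as a centered 0/1 dummy.
    Each class needs n >= 4 samples.
    """
    Xdf = pd.DataFrame(X)
    Xv = Xdf.to_numpy(dtype=float).copy()
    y01, cmap = encode_classes(y)
    if min(np.bincount(y01.astype(int))) < 4:
        raise ValueError("each class needs n >= 4")
    if n_lv < 1:
        raise ValueError("n_lv >= 1 required")
    y_mean = y01.mean()
    f = y01 - y_mean
    n, k = Xv.shape
    ss_x = (Xv ** 2).sum()
    ss_y = (f ** 2).sum()
    W = np.zeros((k, n_lv))
    P = np.zeros((k, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    r2x_cum = np.zeros(n_lv)
    r2y_cum = np.zeros(n_lv)
    for a in range(n_lv):
        u = f.copy()
        w = np.zeros(k)
        for _ in range(max_iter):
            w_new = Xv.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = Xv @ w_new
            qa = float(f @ t / (t @ t))
            u_new = f * qa
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xv @ w
        tt = float(t @ t)
        if tt == 0:
            warnings.warn("degenerate latent variable; stopping early")
            n_lv = a
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            r2x_cum, r2y_cum = r2x_cum[:a], r2y_cum[:a]
            break
        p = Xv.T @ t / tt
        qa = float(f @ t / tt)
        Xv -= np.outer(t, p)
        f = f - t * qa
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        r2x_cum[a] = 1.0 - (Xv ** 2).sum() / ss_x
        r2y_cum[a] = 1.0 - (f ** 2).sum() / ss_y
    model = PLSDAModel(n_lv, W, P, T, q, cmap, list(Xdf.columns),
                       float(y_mean), r2x_cum, r2y_cum)
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """VIP_j = sqrt(K sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a);
    mean(VIP^2) = 1 by construction."""
    W, T, q = model.weights, model.x_scores, model.y_loadings
    k = W.shape[0]
    ssy = q ** 2 * np.einsum("ia,ia->a", T, T)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(k * (wn ** 2 @ ssy) / ssy.sum())


def _stratified_folds(y01: np.ndarray, folds: int, seed: int,
                      stratified: bool = True) -> np.ndarray:
    """Fold id per sample: seeded shuffle within class, dealt round-robin."""
    rng = np.random.default_rng(seed)
    fold_id = np.empty(y01.size, dtype=int)
    if stratified:
        for cls in np.unique(y01):
            idx = np.flatnonzero(y01 == cls)
            rng.shuffle(idx)
            fold_id[idx] = np.arange(idx.size) % folds
    else:
        idx = rng.permutation(y01.size)
        fold_id[idx] = np.arange(y01.size) % folds
        for f in range(folds):
            if len(np.unique(y01[fold_id == f])) < 2:
                warnings.warn(f"fold {f} contains a single class")
    return fold_id


def cross_validated_q2(X, y, n_lv: int, folds: int = 7, seed: int = 0,
                       stratified: bool = True
                       ) -> tuple[float, np.ndarray]:
    """Sevenfold (by default) cross-validated Q2 and per-sample residuals.

    Q2 = 1 - PRESS/SS with PRESS the summed squared out-of-fold prediction
    errors of the full n_lv model and SS the total centered dummy-y sum of
    squares.  Unit-variance scaling is refit on each training fold.
    """
    Xdf = pd.DataFrame(X)
    y01, _ = encode_classes(y)
    if folds < 2:
        raise ValueError("folds >= 2 required")
    if folds > 2 * min(np.bincount(y01.astype(int))):
        raise ValueError("too many folds for the smallest class")
    fold_id = _stratified_folds(y01, folds, seed, stratified)
    y_series = pd.Series(np.asarray(y), index=Xdf.index)
    resid = np.empty(y01.size)
    for f in range(folds):
        test = fold_id == f
        train = ~test
        Xtr, scaler = uv_scale(Xdf.loc[train])
        m = fit_plsda(Xtr, y_series[train].to_numpy(),
                      n_lv=min(n_lv, np.sum(train) - 1, Xtr.shape[1]))
        yhat = m.predict(scaler.transform(Xdf.loc[test]))
        resid[test] = y01[test] - yhat
    press = float((resid ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ss, resid


def cv_anova(cv_residuals, y, n_lv: int = 2,
             method: str = "f", seed: int = 0) -> tuple[float, float]:
    """CV-ANOVA significance of a cross-validated PLS-DA model.

    F compares the drop from total variation to predictive residual
    variation against the residual variation, with Eriksson-style degrees
    of freedom (A, N - A - 1).  ``method="permutation"`` instead compares
    PRESS against a permutation distribution of the class labels.
    """
    resid = np.asarray(cv_residuals, dtype=float)
    y01, _ = encode_classes(y)
    n = resid.size
    press = float((resid ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    if method == "permutation":
        raise ValueError("permutation p needs the full data; use "
                         "fit_plsda_cv(..., validation='permutation')")
    if press >= ss:
        return 0.0, 1.0
    df1 = n_lv
    df2 = n - n_lv - 1
    f_stat = ((ss - press) / df1) / (press / df2)
    return float(f_stat), float(stats.f.sf(f_stat, df1, df2))


def select_n_lv(X, y, max_lv: int = 10, folds: int = 7, seed: int = 0,
                min_gain: float = 0.01) -> int:
    """Smallest number of latent variables maximizing Q2: stop when one
    more LV improves Q2 by less than ``min_gain``."""
    Xdf = pd.DataFrame(X)
    y01, _ = encode_classes(y)
    cap = min(max_lv, Xdf.shape[1], len(Xdf) - 2)
    best_a, best_q2 = 1, -np.inf
    for a in range(1, cap + 1):
        q2, _ = cross_validated_q2(Xdf, y, a, folds=folds, seed=seed)
        if q2 > best_q2 + min_gain:
            best_a, best_q2 = a, q2
        else:
            break
    return best_a


def fit_plsda_cv(features_or_X, y, n_lv: int | None = None, folds: int = 7,
                 seed: int = 0, validation: str = "f",
                 n_perm: int = 200) -> PLSDAModel:
    """Scale, fit, cross-validate and validate a two-class PLS-DA model.

    Accepts a FeatureTable or raw matrix; LV count defaults to the Q2
    maximization policy.  Attaches Q2(cum), VIP and the CV-ANOVA p.
    """
    values = features_or_X.values if hasattr(features_or_X, "metabolites") \
        else pd.DataFrame(features_or_X)
    scaled, scaler = uv_scale(values)
    if n_lv is None:
        n_lv = select_n_lv(values, y, folds=folds, seed=seed)
    model = fit_plsda(scaled, y, n_lv=n_lv)
    q2, resid = cross_validated_q2(values, y, n_lv, folds=folds, seed=seed)
    model.q2_cum = q2
    if validation == "permutation":
        rng = np.random.default_rng(seed)
        press = float((resid ** 2).sum())
        yarr = np.asarray(y)
        worse = 1
        for _ in range(n_perm):
            yp = rng.permutation(yarr)
            try:
                _, rp = cross_validated_q2(values, yp, n_lv, folds=folds,
                                           seed=seed)
            except ValueError:
                continue
            if float((rp ** 2).sum()) <= press:
                worse += 1
        model.cv_anova_p = worse / (n_perm + 1)
    else:
        _, model.cv_anova_p = cv_anova(resid, y, n_lv=n_lv)
    model.cv_config = {"folds": folds, "seed": seed, "stratified": True,
                       "validation": validation}
    return model


# --------------------------------------------------------------------------
# biomarker selection and reporting
# --------------------------------------------------------------------------

def select_discriminant_metabolites(vip, q) -> list[str]:
    """Names with VIP > 1.00 AND q < 0.05, sorted by VIP descending.
    Both thresholds are strict (VIP exactly 1.00 is excluded)."""
    vip = pd.Series(vip)
    q = pd.Series(q)
    if not set(vip.index) == set(q.index):
        raise ValueError("vip and q must cover the same metabolites")
    sel = vip[(vip > 1.00) & (q.reindex(vip.index) < 0.05)]
    return list(sel.sort_values(ascending=False).index)


def model_summary(model, comparison: str = "", n: int | None = None) -> dict:
    """One summary row (comparison, model type, PC/LV, N, R2X(cum),
    R2Y(cum), Q2(cum), CV-ANOVA p); PCA rows leave the supervised fields
    as '-'."""
    if isinstance(model, PCAModel):
        return {"comparison": comparison, "model_type": "PCA",
                "pc_lv": model.n_pc,
                "N": n if n is not None else model.scores.shape[0],
                "r2x_cum": round(float(model.r2x_cum[-1]), 3),
                "r2y_cum": "-", "q2_cum": "-", "cv_anova_p": "-"}
    return {"comparison": comparison, "model_type": "PLS-DA",
            "pc_lv": model.n_lv,
            "N": n if n is not None else model.x_scores.shape[0],
            "r2x_cum": round(float(model.r2x_cum[-1]), 3),
            "r2y_cum": round(float(model.r2y_cum[-1]), 3),
            "q2_cum": round(float(model.q2_cum), 3)
            if np.isfinite(model.q2_cum) else "-",
            "cv_anova_p": float(model.cv_anova_p)
            if np.isfinite(model.cv_anova_p) else "-"}


def score_plot(model, labels, path=None, ax=None):
    """Scores of the first two components with the 95% Hotelling ellipse."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    scores = model.scores if isinstance(model, PCAModel) else model.x_scores
    if scores.shape[1] < 2:
        raise ValueError("need at least two components to plot")
    ell = hotelling_ellipse(scores)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for lab in pd.unique(np.asarray(labels)):
        m = np.asarray(labels) == lab
        ax.scatter(scores[m, 0], scores[m, 1], label=str(lab), s=18)
    th = np.linspace(0, 2 * np.pi, 200)
    ax.plot(ell.center[0] + ell.semi_axes[0] * np.cos(th),
            ell.center[1] + ell.semi_axes[1] * np.sin(th),
            "k--", lw=1, label="Hotelling T2 95%")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=110)
        plt.close(ax.figure)
    return ax
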