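"""Chemometrics: column scaling, PCA, and two-class OPLS-DA, from scratch.

Scaling follows the SIMCA conventions: Pareto divides each centered column
by the square root of its (ddof=1) standard deviation, UV by the standard
deviation itself. PCA is computed by singular value decomposition of the
scaled matrix; explained-variance fractions are eigenvalue ratios.

OPLS-DA separates the variation in X that is predictive of the two-class
response from variation orthogonal to it (Trygg-Wold orthogonal
projections to latent structures): each orthogonal component is found by
deflating the PLS loading of its y-correlated part, after which a single
predictive PLS component is fit to the deflated X. Model quality is
summarized by R2X (X variance captured by all components), R2Y (y variance
captured by the predictive component) and Q2 (cross-validated
predictability, 1 - PRESS/SS, 7-fold venetian-blind by default). Variable
influence is summarized by VIP (mean square 1 by construction; VIP > 1 is
the conventional selection rule) and by the S-line: the covariance of each
scaled variable with the predictive score (magnitude) colored by the
Pearson correlation.

The predictive component is oriented so the positive class (treated group)
has a positive mean score, making S-line signs reproducible: positive
covariance = higher in the treated class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np


@dataclass
class ScaledMatrix:
    values: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    mode: str
    zero_variance_columns: list[int] = dc_field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.values * self.scales + self.means


def scale_columns(matrix: np.ndarray, mode: str = "pareto") -> ScaledMatrix:
    """Center and scale columns: 'pareto' (1/sqrt(sd)), 'uv' (1/sd), 'none'.

    Standard deviations use ddof=1. Zero-variance columns are centered
    only (scale 1) and reported in ``zero_variance_columns`` with a
    warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2D")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to estimate column variance")
    if mode not in ("pareto", "uv", "none"):
        raise ValueError("mode must be 'pareto', 'uv' or 'none'")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        warnings.warn(f"{zero.size} zero-variance column(s) centered only",
                      stacklevel=2)
    if mode == "none":
        scales = np.ones_like(sd)
    elif mode == "uv":
        scales = np.where(sd > 0, sd, 1.0)
    else:
        scales = np.where(sd > 0, np.sqrt(sd), 1.0)
    return ScaledMatrix((X - means) / scales, means, scales, mode,
                        list(map(int, zero)))


@dataclass
class PCAModel:
    scores: np.ndarray     # samples x components (U S)
    loadings: np.ndarray   # variables x components (V)
    explained_variance_fraction: np.ndarray


def fit_pca(scaled: ScaledMatrix | np.ndarray, n_components: int = 2) -> PCAModel:
    """Principal axes of the (already centered/scaled) matrix via SVD."""
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled)
    r_max = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max(r_max, 1)):
        raise ValueError(f"n_components must be in [1, {r_max}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    total = lam.sum()
    frac = lam / total if total > 0 else lam
    k = n_components
    return PCAModel(U[:, :k] * s[:k], Vt[:k].T, frac[:k])


@dataclass
class OPLSModel:
    scores_pred: np.ndarray      # t, predictive scores
    loadings_pred: np.ndarray    # p
    weights_pred: np.ndarray     # w (unit norm)
    c_pred: float                # y loading
    scores_ortho: np.ndarray     # samples x n_ortho
    loadings_ortho: np.ndarray   # variables x n_ortho
    weights_ortho: np.ndarray    # variables x n_ortho
    r2x: float
    r2y: float
    q2: float
    y: np.ndarray                # centered +-1 coding used in the fit
    classes: tuple               # (negative class, positive class)

    def predict_scores(self, X_new: np.ndarray) -> np.ndarray:
        """Orthogonal-filter new (scaled) rows and project onto w."""
        X = np.array(X_new, dtype=float, copy=True)
        for k in range(self.weights_ortho.shape[1]):
            t_o = X @ self.weights_ortho[:, k]
            X -= np.outer(t_o, self.loadings_ortho[:, k])
        return X @ self.weights_pred

    def predict_y(self, X_new: np.ndarray) -> np.ndarray:
        return self.predict_scores(X_new) * self.c_pred


def _encode_y(y) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(y)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    coded = np.where(labels == classes[1], 1.0, -1.0)
    return coded - coded.mean(), classes


def _opls_core(X: np.ndarray, yc: np.ndarray, n_ortho: int):
    """One pass of the O-PLS algorithm; returns component matrices."""
    w = X.T @ yc / (yc @ yc)
    w /= np.linalg.norm(w)
    Xr = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    c = (yc @ t) / (t @ t)
    stack = (lambda L: np.column_stack(L) if L
             else np.empty((X.shape[1], 0)))
    T_o_m = np.column_stack(T_o) if T_o else np.empty((X.shape[0], 0))
    return w, t, p, c, stack(W_o), stack(P_o), T_o_m


def venetian_blind_folds(n: int, folds: int, seed: int | None = None) -> np.ndarray:
    """Fold assignment i -> i mod folds, optionally over a seeded order."""
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    out = np.empty(n, dtype=int)
    out[order] = np.arange(n) % folds
    return out


def fit_oplsda(scaled: ScaledMatrix | np.ndarray, y, n_ortho: int = 1,
               cv_folds: int = 7, cv_seed: int | None = None,
               fold_assignment: np.ndarray | None = None) -> OPLSModel:
    """Two-class OPLS-DA with k-fold cross-validated Q2.

    y holds two class labels; they are coded +-1 and centered. The
    positive class is the lexicographically larger label and the
    predictive component is oriented so its mean score is positive.
    """
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled, float)
    yc, classes = _encode_y(y)
    labels = np.asarray(y)
    n = X.shape[0]
    for cls in classes:
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls!r} has < 2 members; CV infeasible")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")

    w, t, p, c, W_o, P_o, T_o = _opls_core(X, yc, n_ortho)

    ssx = np.sum(X**2)
    X_expl = np.outer(t, p)
    for k in range(T_o.shape[1]):
        X_expl += np.outer(T_o[:, k], P_o[:, k])
    r2x = float(np.sum(X_expl**2) / ssx)
    ssy = float(yc @ yc)
    r2y = float(1.0 - np.sum((yc - t * c)**2) / ssy)

    # cross-validated Q2
    if fold_assignment is None:
        fold_assignment = venetian_blind_folds(n, cv_folds, cv_seed)
    press = 0.0
    for f in np.unique(fold_assignment):
        test = fold_assignment == f
        train = ~test
        if len(set(labels[train])) < 2:
            raise ValueError("a CV fold lost one class entirely")
        yc_tr = np.where(labels[train] == classes[1], 1.0, -1.0)
        yc_tr = yc_tr - yc_tr.mean()
        w_f, t_f, p_f, c_f, W_of, P_of, _ = _opls_core(X[train], yc_tr, n_ortho)
        Xt = np.array(X[test], copy=True)
        for k in range(W_of.shape[1]):
            t_o = Xt @ W_of[:, k]
            Xt -= np.outer(t_o, P_of[:, k])
        y_hat = (Xt @ w_f) * c_f
        press += float(np.sum((yc[test] - y_hat)**2))
    q2 = float(1.0 - press / ssy)

    # orient: positive class mean score positive
    if t[labels == classes[1]].mean() < 0:
        w, t, p, c = -w, -t, -p, -c
    return OPLSModel(t, p, w, float(c), T_o, P_o, W_o,
                     r2x, r2y, q2, yc, classes)


def vip_scores(model: OPLSModel) -> np.ndarray:
    """VIP of the predictive component: sqrt(p_vars) |w| / ||w||.

    Satisfies sum(VIP^2) = number of variables exactly.
    """
    w = model.weights_pred
    p_vars = w.size
    return np.sqrt(p_vars) * np.abs(w) / np.linalg.norm(w)


def s_line(model: OPLSModel, scaled: ScaledMatrix | np.ndarray):
    """Per-variable (covariance, correlation) with the predictive score.

    Positive covariance means higher intensity in the positive (treated)
    class. Variables with zero variance get correlation 0.
    """
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled, float)
    t = model.scores_pred
    n = t.size
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sd_x = Xc.std(axis=0, ddof=1)
    sd_t = tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_x * sd_t), 0.0)
    return cov, corr


def permutation_q2(scaled: ScaledMatrix | np.ndarray, y, n_ortho: int = 1,
                   n_permutations: int = 100, seed: int = 0,
                   cv_folds: int = 7) -> np.ndarray:
    """Q2 values under random label permutation (model-validity check)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(y)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels.size)
        while len(set(labels[perm].tolist())) < 2:  # pragma: no cover
            perm = rng.permutation(labels.size)
        try:
            out[i] = fit_oplsda(scaled, labels[perm], n_ortho=n_ortho,
                                cv_folds=cv_folds).q2
        except ValueError:
            out[i] = np.nan
    return out
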