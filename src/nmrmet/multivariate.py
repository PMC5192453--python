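"""Latent-variable modelling: NIPALS PCA, PLS2, two-class OPLS, leave-one-out
Q2Y, permutation validation, CV-ANOVA and correlation loadings.

All fitting routines are written from scratch on numpy primitives; scaling
is refit inside every cross-validation fold (train-fold means/sds applied
to the held-out sample) so no information leaks from the left-out sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocess import BucketTable

__all__ = [
    "ResponseMatrix",
    "ModelSpec",
    "LatentModel",
    "CVResult",
    "ValidationReport",
    "LoadingProfile",
    "fit_pca",
    "fit_pls",
    "fit_opls",
    "q2y_loo",
    "permutation_test",
    "cv_anova",
    "correlation_loadings",
    "select_discriminant",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, BucketTable):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class ResponseMatrix:
    """Group labels encoded as a dummy matrix (one column per class)."""

    sample_ids: list[str]
    labels: list[str]
    classes: list[str]
    Y: np.ndarray

    @classmethod
    def from_labels(cls, sample_ids: Sequence[str], labels: Sequence[str]) -> "ResponseMatrix":
        labels = [str(l) for l in labels]
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError("need at least 2 distinct labels")
        Y = np.zeros((len(labels), len(classes)))
        for i, lab in enumerate(labels):
            Y[i, classes.index(lab)] = 1.0
        return cls(list(sample_ids), labels, classes, Y)

    def binary(self, negative: str, positive: str) -> np.ndarray:
        """Two-class -1/+1 coding; ``positive`` is the class coded +1."""
        for c in (negative, positive):
            if c not in self.classes:
                raise ValueError(f"class {c!r} not present")
        y = np.empty(len(self.labels))
        for i, lab in enumerate(self.labels):
            if lab == positive:
                y[i] = 1.0
            elif lab == negative:
                y[i] = -1.0
            else:
                raise ValueError(f"sample {self.sample_ids[i]!r} has label {lab!r} outside the contrast")
        return y


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: model kind plus component counts."""

    kind: str = "opls"  # {"pca", "pls", "opls"}
    n_predictive: int = 1
    n_orthogonal: int = 0

    @property
    def n_components(self) -> int:
        return self.n_predictive + self.n_orthogonal


@dataclass
class LatentModel:
    kind: str
    n_predictive: int
    n_orthogonal: int
    T_pred: np.ndarray  # samples x predictive components
    P: np.ndarray  # variables x predictive components
    W: np.ndarray  # variables x predictive components
    C: np.ndarray | None = None  # responses x predictive components
    T_orth: np.ndarray | None = None
    P_orth: np.ndarray | None = None
    W_orth: np.ndarray | None = None
    R2Y: float | None = None
    Q2Y: float | None = None
    explained_variance_ratio: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    def predict(self, X_scaled) -> np.ndarray:
        """Predict the (centered-scale) response for already-scaled rows."""
        X = np.atleast_2d(_as_matrix(X_scaled)).copy()
        if self.kind == "pca":
            raise ValueError("PCA has no response to predict")
        if self.kind == "opls":
            for k in range(self.n_orthogonal):
                t_o = X @ self.W_orth[:, k]
                X = X - np.outer(t_o, self.P_orth[:, k])
            t = X @ self.W[:, 0]
            return np.outer(t, self.C[:, 0]) + self.y_mean
        # PLS2 regression coefficients
        B = self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)
        return X @ B + self.y_mean

    def scores(self, X_scaled) -> np.ndarray:
        X = np.atleast_2d(_as_matrix(X_scaled)).copy()
        if self.kind == "opls":
            for k in range(self.n_orthogonal):
                t_o = X @ self.W_orth[:, k]
                X = X - np.outer(t_o, self.P_orth[:, k])
        return X @ self.W


@dataclass
class CVResult:
    """Leave-one-out cross-validation output."""

    q2y: float
    press: float
    ss_total: float
    n_samples: int
    spec: ModelSpec
    predictions: np.ndarray


@dataclass
class ValidationReport:
    n_permutations: int
    permuted_Q2Y: np.ndarray
    percentile_99: float
    observed_Q2Y: float
    passes: bool
    p_value: float
    cv_anova_p: float | None
    seed: int

    def __post_init__(self) -> None:
        assert len(self.permuted_Q2Y) == self.n_permutations
        assert self.passes == (self.observed_Q2Y > self.percentile_99)


@dataclass
class LoadingProfile:
    bucket_centers: np.ndarray
    covariance: np.ndarray
    R: np.ndarray
    zero_variance: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.R) > 1 + 1e-9):
            raise ValueError("|R| exceeds 1")


# ---------------------------------------------------------------------------
# PCA


def fit_pca(X, n_components: int) -> LatentModel:
    """NIPALS principal component analysis of a column-centered matrix.

    ``X`` is used as given (center/scale with :func:`nmrmet.preprocess.scale`
    first for the standard pipeline).
    """
    Xd = _as_matrix(X).copy()
    n, p = Xd.shape
    max_rank = min(n - 1, p)
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    ss_total = float(np.sum(Xd**2))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    evr = np.zeros(n_components)
    for a in range(n_components):
        t = Xd[:, int(np.argmax(Xd.var(axis=0)))].copy()
        if np.allclose(t, 0):
            break
        for _ in range(_NIPALS_MAX_ITER):
            pv = Xd.T @ t / (t @ t)
            pv /= np.linalg.norm(pv)
            t_new = Xd @ pv
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        T[:, a] = t
        P[:, a] = pv
        Xd -= np.outer(t, pv)
        evr[a] = (t @ t) / ss_total if ss_total > 0 else 0.0
    return LatentModel(
        kind="pca",
        n_predictive=n_components,
        n_orthogonal=0,
        T_pred=T,
        P=P,
        W=P,
        explained_variance_ratio=evr,
    )


def score_distances(model: LatentModel) -> np.ndarray:
    """Hotelling-style normalized score distance per sample."""
    T = model.T_pred
    var = T.var(axis=0, ddof=1)
    var[var == 0] = 1.0
    return np.sqrt(((T**2) / var).sum(axis=1))


# ---------------------------------------------------------------------------
# PLS


def _center_Y(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    mean = Y.mean(axis=0)
    return Y - mean, mean


def fit_pls(X, Y, n_components: int) -> LatentModel:
    """NIPALS PLS2 regression of a (dummy) response on the scaled matrix."""
    Xd = _as_matrix(X).copy()
    if isinstance(Y, ResponseMatrix):
        Y = Y.Y
    Yc, y_mean = _center_Y(Y)
    n, p = Xd.shape
    if Yc.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if np.allclose(Yc, 0):
        raise ValueError("constant response")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    ss_y = float(np.sum(Yc**2))
    Yd = Yc.copy()
    k = Yc.shape[1]
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((k, n_components))
    for a in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        t = np.zeros(n)
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = Xd @ w
            c = Yd.T @ t_new / (t_new @ t_new)
            if np.linalg.norm(c) == 0:
                t = t_new
                break
            u = Yd @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        if np.allclose(t, 0):
            warnings.warn(f"PLS stopped early at component {a + 1}: no covariance left")
            T, W, P, C = T[:, :a], W[:, :a], P[:, :a], C[:, :a]
            break
        pv = Xd.T @ t / (t @ t)
        c = Yd.T @ t / (t @ t)
        Xd -= np.outer(t, pv)
        Yd -= np.outer(t, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, pv, c
    r2y = 1.0 - float(np.sum(Yd**2)) / ss_y
    return LatentModel(
        kind="pls",
        n_predictive=T.shape[1],
        n_orthogonal=0,
        T_pred=T,
        P=P,
        W=W,
        C=C,
        R2Y=r2y,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# OPLS (two-class)


def fit_opls(X, y, n_orthogonal: int = 0) -> LatentModel:
    """Two-class OPLS: orthogonal-variation filtering then one predictive
    component.

    Per orthogonal round: p = X't/t't, w_orth = p - (w'p)w (normalized),
    t_orth = X w_orth, and X is deflated by t_orth p_orth'.  The predictive
    component is fitted on the filtered matrix.
    """
    Xd = _as_matrix(X).copy()
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xd.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if np.unique(y).size != 2:
        raise ValueError("OPLS requires exactly two classes")
    if n_orthogonal < 0 or n_orthogonal >= n - 2:
        raise ValueError(f"n_orthogonal must be in [0, {n - 3}]")
    y_mean = y.mean()
    yc = y - y_mean
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        # no covariance anywhere (e.g. constant X): degenerate model that
        # predicts the mean, so Q2Y is identical under any permutation
        warnings.warn("response carries no covariance with X; fitting a mean-only model")
        w = np.zeros(p)
        w[0] = 1.0
        n_orthogonal = 0
    else:
        w /= nw
    T_orth = np.zeros((n, n_orthogonal))
    P_orth = np.zeros((p, n_orthogonal))
    W_orth = np.zeros((p, n_orthogonal))
    for k in range(n_orthogonal):
        t = Xd @ w
        pv = Xd.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        n_o = np.linalg.norm(w_o)
        if n_o <= 1e-14:
            warnings.warn(f"no orthogonal variation left at component {k + 1}")
            T_orth, P_orth, W_orth = T_orth[:, :k], P_orth[:, :k], W_orth[:, :k]
            n_orthogonal = k
            break
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        T_orth[:, k], P_orth[:, k], W_orth[:, k] = t_o, p_o, w_o
    t = Xd @ w
    tt = float(t @ t)
    if tt > 0:
        pv = Xd.T @ t / tt
        c = float(yc @ t / tt)
    else:
        pv = np.zeros(p)
        c = 0.0
    resid = yc - t * c
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    return LatentModel(
        kind="opls",
        n_predictive=1,
        n_orthogonal=n_orthogonal,
        T_pred=t[:, None],
        P=pv[:, None],
        W=w[:, None],
        C=np.array([[c]]),
        T_orth=T_orth,
        P_orth=P_orth,
        W_orth=W_orth,
        R2Y=r2y,
        y_mean=np.array([y_mean]),
    )


def fit_model(X, Y, spec: ModelSpec) -> LatentModel:
    """Dispatch on :class:`ModelSpec`."""
    if spec.kind == "pca":
        return fit_pca(X, spec.n_predictive)
    if spec.kind == "pls":
        return fit_pls(X, Y, spec.n_predictive)
    if spec.kind == "opls":
        return fit_opls(X, Y, spec.n_orthogonal)
    raise ValueError(f"unknown model kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Cross-validation, permutation, CV-ANOVA


def _scale_fold(X_train: np.ndarray, x_test: np.ndarray, method: str):
    mean = X_train.mean(axis=0)
    if method == "center":
        return X_train - mean, x_test - mean
    sd = X_train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X_train - mean) / sd, (x_test - mean) / sd


def loo_folds(X_unscaled, scaling: str = "center_unit_variance"):
    """Precompute per-fold scaled matrices (independent of the response)."""
    X = _as_matrix(X_unscaled)
    n = X.shape[0]
    folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, xte = _scale_fold(X[mask], X[i], scaling)
        folds.append((mask, Xtr, xte))
    return folds


def _q2_from_folds(folds, Y: np.ndarray, spec: ModelSpec) -> CVResult:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 samples")
    press = 0.0
    # total corrected sum of squares (the SIMCA-style reference for Q2);
    # PRESS carries the fold-mean offset, so null models land below zero
    ss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    preds = np.zeros_like(Y)
    for i, (mask, Xtr, xte) in enumerate(folds):
        Ytr = Y[mask]
        if spec.kind == "opls" and np.unique(Ytr[:, 0]).size < 2:
            raise ValueError(f"fold {i} drops an entire class; cannot cross-validate")
        if spec.kind == "pls" and np.allclose(Ytr - Ytr.mean(axis=0), 0):
            raise ValueError(f"fold {i} has a constant response; cannot cross-validate")
        yhat = fit_model(Xtr, Ytr if spec.kind == "pls" else Ytr[:, 0], spec).predict(xte)
        preds[i] = yhat
        press += float(np.sum((Y[i] - yhat) ** 2))
    q2 = 1.0 - press / ss
    return CVResult(q2y=q2, press=press, ss_total=ss, n_samples=n, spec=spec, predictions=preds)


def q2y_loo(X_unscaled, Y, spec: ModelSpec, scaling: str = "center_unit_variance") -> CVResult:
    """Leave-one-out Q2Y with per-fold re-centering/scaling.

    ``X_unscaled`` is the normalized (e.g. PQN) but unscaled matrix; each
    fold scales on its own training rows.  ``Y`` is a dummy matrix (pls) or
    two-class vector (opls).
    """
    if isinstance(Y, ResponseMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    folds = loo_folds(X_unscaled, scaling)
    return _q2_from_folds(folds, Y, spec)


def cv_anova(cv: CVResult, n_components: int | None = None) -> float:
    """F-test of the cross-validated predictive residuals against the total
    corrected sum of squares (df_model = components, df_resid = n - components - 1)."""
    k = cv.spec.n_components if n_components is None else n_components
    n = cv.n_samples
    df_model = k
    df_resid = n - k - 1
    if df_model < 1 or df_resid < 1:
        raise ValueError("not enough samples for CV-ANOVA degrees of freedom")
    if cv.press <= 0:
        warnings.warn("zero cross-validated residual; p at numeric lower bound")
        return float(np.finfo(float).tiny)
    if cv.press >= cv.ss_total:
        return 1.0
    F = ((cv.ss_total - cv.press) / df_model) / (cv.press / df_resid)
    return float(stats.f.sf(F, df_model, df_resid))


def permutation_test(
    X_unscaled,
    Y,
    spec: ModelSpec,
    n_permutations: int = 999,
    seed: int = 0,
    scaling: str = "center_unit_variance",
    with_cv_anova: bool = True,
) -> ValidationReport:
    """Label-permutation null distribution of Q2Y.

    The model (and its LOO Q2Y, with fold-wise rescaling) is refitted for
    each of ``n_permutations`` row-shuffles of the response; the observed
    model passes when its Q2Y exceeds the empirical 99th percentile.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: the 99th percentile is unstable")
    if isinstance(Y, ResponseMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    folds = loo_folds(X_unscaled, scaling)
    observed_cv = _q2_from_folds(folds, Y, spec)
    rng = np.random.default_rng(seed)
    perm_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        Yb = Y[rng.permutation(Y.shape[0])]
        try:
            perm_q2[b] = _q2_from_folds(folds, Yb, spec).q2y
        except ValueError:
            perm_q2[b] = -np.inf  # degenerate permutation fold; counts as no skill
    pct99 = float(np.percentile(perm_q2, 99))
    observed = observed_cv.q2y
    p_val = (1.0 + float(np.sum(perm_q2 >= observed))) / (n_permutations + 1.0)
    return ValidationReport(
        n_permutations=n_permutations,
        permuted_Q2Y=perm_q2,
        percentile_99=pct99,
        observed_Q2Y=observed,
        passes=bool(observed > pct99),
        p_value=p_val,
        cv_anova_p=cv_anova(observed_cv) if with_cv_anova else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Correlation loadings and discriminant-metabolite selection


def correlation_loadings(X, y, bucket_centers=None) -> LoadingProfile:
    """Per-bucket covariance and Pearson correlation with the class coding.

    Positive R means higher intensity in the class coded +1.  Zero-variance
    buckets get R = 0 and are flagged.
    """
    if isinstance(X, BucketTable):
        centers = X.bucket_centers
        V = X.values
    else:
        V = np.asarray(X, dtype=float)
        centers = np.asarray(bucket_centers if bucket_centers is not None else np.arange(V.shape[1]), dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = V.shape[0]
    if y.size != n:
        raise ValueError("X and y row counts differ")
    xc = V - V.mean(axis=0)
    yc = y - y.mean()
    cov = xc.T @ yc / (n - 1)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    zero_var = sx < 1e-12 * max(1.0, float(np.abs(V).max()))
    denom = np.where(zero_var, 1.0, sx * sy)
    R = np.where(zero_var, 0.0, xc.T @ yc / denom)
    R = np.clip(R, -1.0, 1.0)
    return LoadingProfile(bucket_centers=centers, covariance=cov, R=R, zero_variance=zero_var)


def select_discriminant(
    profile: LoadingProfile,
    assignments: Mapping[str, Sequence[int]],
    threshold: float = 0.5,
    intensities: np.ndarray | None = None,
    min_rel_intensity: float = 0.25,
) -> list[tuple[str, float]]:
    """Metabolite-level discriminant selection.

    ``assignments`` maps metabolite name -> indices of its assigned buckets
    in the profile.  The metabolite-level R is the signed R of its
    maximal-|R| bucket (ties broken toward lower ppm); a metabolite is
    selected when |R| >= threshold (inclusive).  Output sorted by |R|
    descending, ties by name.

    When per-bucket ``intensities`` (typically the cohort median spectrum)
    are given, only buckets reaching ``min_rel_intensity`` of the strongest
    assigned bucket of that metabolite are considered: annotation windows
    cover baseline buckets whose correlations are pure noise, and a peak
    must actually rise from the baseline to be read off a loading plot.
    """
    out: list[tuple[str, float]] = []
    for name, idx in assignments.items():
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            warnings.warn(f"metabolite {name!r} has no assigned bucket in the table; skipped")
            continue
        order = np.argsort(profile.bucket_centers[idx], kind="stable")
        idx = idx[order]
        if intensities is not None:
            height = np.asarray(intensities, dtype=float)[idx]
            keep = height >= min_rel_intensity * height.max()
            if keep.any():
                idx = idx[keep]
        best = idx[int(np.argmax(np.abs(profile.R[idx])))]
        r = float(profile.R[best])
        if abs(r) >= threshold:
            out.append((name, r))
    out.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    return out
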