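"""PCA, NIPALS partial least squares, VIP, Q2 and permutation testing.

This is the statistical engine behind marker selection, core-hybrid
selection and the prediction equation.  PLS1 is implemented with the
classical NIPALS deflation scheme: for each latent factor a unit weight
vector ``w_a`` proportional to ``X'y`` is extracted, scores ``t_a = X w_a``
are computed, X and y are deflated by their regression on ``t_a``, and the
procedure repeats on the residuals.  Coefficients on the original predictor
scale are recovered through ``R = W (P'W)^{-1}``, so a fitted model predicts
as ``b0 + X B`` without re-running the deflation.

Variable importance in projection (VIP) follows Wold's definition: the
contribution of each predictor to the explained response variance,
normalised so the mean squared VIP over predictors equals one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PCAResult",
    "PLSModel",
    "DAResult",
    "pca",
    "fit_pls",
    "max_components",
    "adjusted_r2",
    "select_n_components",
    "vip",
    "fit_plsda",
    "permutation_test",
]

# relative tolerance deciding when the X'y covariance or a score vector has
# collapsed and no further latent factor can be extracted
_DEGENERACY_RTOL = 1e-12


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """SVD-based principal components of a column-centred matrix.

    Loading columns are orthonormal; each is oriented so its
    largest-magnitude entry is positive, which pins down the otherwise
    arbitrary sign and makes PC1-score rankings reproducible.
    """

    scores: np.ndarray              # samples x components (U * S)
    loadings: np.ndarray            # variables x components, orthonormal
    explained_variance: np.ndarray  # per-component proportion of total variance


def pca(X, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of ``X`` (centred internally)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    k_full = len(s)
    k = k_full if n_components is None else min(int(n_components), k_full)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    if total > 0:
        explained = (s[:k] ** 2) / total
    else:
        explained = np.zeros(k)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=explained)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS1 regression model.

    ``coef``/``intercept`` predict on the original predictor scale;
    ``x_weights``/``x_loadings``/``y_loadings`` hold the factor-form
    parameters, which give identical predictions (see
    :meth:`predict_factors`).  ``vip`` is computed over all extracted
    components; :meth:`vip_for` restricts to the leading components.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray      # W, p x A, unit-norm columns
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # q, (A,)
    x_scores: np.ndarray       # T, n x A, mutually orthogonal
    coef: np.ndarray           # B, (p,)
    intercept: float           # b0
    r2: float
    adjusted_r2: float
    vip: np.ndarray            # (p,), all components
    feature_names: list | None = None

    @property
    def n_samples(self) -> int:
        return self.x_scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.coef.shape[0]

    def predict(self, X) -> np.ndarray:
        """b0 + X B on the original predictor scale."""
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept

    def predict_factors(self, X) -> np.ndarray:
        """Prediction reconstructed from the factor form (W, P, q)."""
        X = np.asarray(X, dtype=float)
        if self.n_components == 0:
            return np.full(X.shape[0], self.y_mean)
        R = _rotations(self.x_weights, self.x_loadings)
        T = (X - self.x_mean) @ R
        return self.y_mean + T @ self.y_loadings

    def vip_for(self, components: int) -> np.ndarray:
        """VIP restricted to the first ``components`` latent factors."""
        return vip(self, components)

    def to_dict(self) -> dict:
        """JSON-serialisable representation (round-trips via from_dict)."""
        return {
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "x_scores": self.x_scores.tolist(),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "adjusted_r2": float(self.adjusted_r2),
            "vip": self.vip.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PLSModel":
        arrays = {
            k: np.asarray(payload[k], dtype=float)
            for k in ("x_mean", "x_weights", "x_loadings", "y_loadings",
                      "x_scores", "coef", "vip")
        }
        return cls(
            n_components=int(payload["n_components"]),
            y_mean=float(payload["y_mean"]),
            intercept=float(payload["intercept"]),
            r2=float(payload["r2"]),
            adjusted_r2=float(payload["adjusted_r2"]),
            feature_names=payload.get("feature_names"),
            **arrays,
        )


def _rotations(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """R = W (P'W)^{-1}, mapping centred X to scores without deflation."""
    return W @ np.linalg.inv(P.T @ W)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Run NIPALS deflation, returning (W, P, q, T) with <= n_components columns."""
    n, p = Xc.shape
    scale = float(np.linalg.norm(Xc) * np.linalg.norm(yc))
    x_scale2 = float(np.linalg.norm(Xc) ** 2)
    Xr = Xc.copy()
    yr = yc.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        c = Xr.T @ yr
        nc = float(np.linalg.norm(c))
        if nc <= _DEGENERACY_RTOL * max(scale, 1e-300):
            break
        w = c / nc
        t = Xr @ w
        tt = float(t @ t)
        if tt <= _DEGENERACY_RTOL * max(x_scale2, 1e-300):
            break
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t) / tt
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W.append(w)
        P.append(p_a)
        Q.append(q_a)
        T.append(t)
    a = len(W)
    W = np.column_stack(W) if a else np.zeros((p, 0))
    P = np.column_stack(P) if a else np.zeros((p, 0))
    T = np.column_stack(T) if a else np.zeros((n, 0))
    q = np.asarray(Q, dtype=float)
    return W, P, q, T


def max_components(X, y) -> int:
    """Number of latent factors extractable from (X, y) before degeneracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cap = min(n - 1, p)
    if cap < 1:
        return 0
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, _, _, _ = _nipals(Xc, yc, cap)
    return W.shape[1]


def _vip_from_parts(W: np.ndarray, T: np.ndarray, q: np.ndarray,
                    components: int) -> np.ndarray:
    p = W.shape[0]
    a = components
    if a == 0:
        return np.zeros(p)
    ssy = q[:a] ** 2 * np.einsum("ij,ij->j", T[:, :a], T[:, :a])
    total = float(ssy.sum())
    if total <= 0:
        return np.zeros(p)
    return np.sqrt(p * (W[:, :a] ** 2 @ ssy) / total)


def fit_pls(X, y, n_components: int, feature_names=None,
            allow_fewer: bool = False) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_components`` latent factors.

    Raises if more factors are requested than the data can supply (the cap
    is ``min(n - 1, p)`` further limited by deflation running dry); with
    ``allow_fewer=True`` the model is truncated instead, which is what
    cross-validation folds and permutation replicates use.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    hard_cap = min(n - 1, p)
    if n_components > hard_cap and not allow_fewer:
        raise ValueError(
            f"no more than {hard_cap} latent factors can be extracted from "
            f"{n} samples x {p} predictors (requested {n_components})"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T = _nipals(Xc, yc, min(n_components, hard_cap))
    a = W.shape[1]
    if a < n_components and not allow_fewer:
        raise ValueError(
            f"no more than {a} latent factors could be extracted "
            f"(requested {n_components})"
        )
    if a == 0:
        coef = np.zeros(p)
        intercept = y_mean
    else:
        coef = _rotations(W, P) @ q
        intercept = y_mean - float(x_mean @ coef)
    yhat = X @ coef + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = adjusted_r2(r2, n, a) if (a >= 1 and n > a + 1) else float("nan")
    model = PLSModel(
        n_components=a,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef=coef,
        intercept=float(intercept),
        r2=r2,
        adjusted_r2=adj,
        vip=_vip_from_parts(W, T, q, a),
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    return model


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1 - r2) (n - 1) / (n - k - 1) with k = number of latent factors."""
    if n <= k + 1:
        raise ValueError(f"adjusted R2 requires n > k + 1 (got n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def select_n_components(X, y, a_max: int):
    """Choose the latent-factor count by the peak of training adjusted R2.

    Fits models with 1..``a_max`` factors (capped at what the data support:
    at most n - 2 so adjusted R2 is defined, and at most the number of
    factors deflation can extract) and returns ``(A*, adjusted_r2_path)``
    with ties going to the smaller count.  A response carrying no covariance
    with X (e.g. a constant y) yields ``(1, [0.0])``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    a_max = int(a_max)
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    cap = min(a_max, n - 2, p)
    if cap < 1:
        raise ValueError(f"too few samples (n={n}) to select a latent-factor count")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T = _nipals(Xc, yc, cap)
    a_got = W.shape[1]
    if a_got == 0:
        return 1, np.zeros(1)
    ss_tot = float((yc ** 2).sum())
    path = np.empty(a_got)
    for a in range(1, a_got + 1):
        coef = _rotations(W[:, :a], P[:, :a]) @ q[:a]
        resid = yc - Xc @ coef
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        path[a - 1] = adjusted_r2(r2, n, a)
    a_star = int(np.argmax(path)) + 1   # first occurrence = smallest tie
    return a_star, path


def vip(model: PLSModel, components: int | None = None) -> np.ndarray:
    """Wold VIP of each predictor over the first ``components`` factors.

    For ``components=1`` this reduces to ``sqrt(p) |w_j1| / ||w_1||``.  The
    mean squared VIP over predictors is exactly 1 for any fitted model.
    """
    if components is None:
        components = model.n_components
    components = int(components)
    if components > model.n_components:
        raise ValueError(
            f"model has {model.n_components} components; requested {components}"
        )
    return _vip_from_parts(model.x_weights, model.x_scores,
                           model.y_loadings, components)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class DAResult:
    """PLS discriminant analysis on a two-class label vector.

    Classes are coded 0/1 (``classes[1]`` -> 1) and fitted with PLS1.  Q2 is
    the cross-validated predictive ability 1 - PRESS/TSS over stratified
    held-out folds.  ``permutation_p`` is filled in by
    :func:`permutation_test` when requested.
    """

    model: PLSModel
    q2: float
    component1_vip: np.ndarray
    classes: tuple
    permutation_p: float | None = None


def _code_labels(labels):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(f"PLS-DA needs exactly 2 classes, got {classes.shape[0]}")
    y = (labels == classes[1]).astype(float)
    return y, tuple(classes.tolist())


def fit_plsda(X, labels, n_components: int = 2, cv_folds: int = 10,
              seed: int = 0, feature_names=None) -> DAResult:
    """Fit PLS-DA and estimate Q2 by stratified k-fold cross-validation.

    Each class must have at least 3 samples.  Fold models reuse the global
    column scaling of ``X`` (the matrix is expected to be preprocessed
    upstream); only the PLS fit itself is re-estimated per fold.
    """
    X = np.asarray(X, dtype=float)
    y, classes = _code_labels(labels)
    counts = np.bincount(y.astype(int))
    if counts.min() < 3:
        raise ValueError("PLS-DA needs at least 3 samples per class")
    model = fit_pls(X, y, n_components, feature_names=feature_names,
                    allow_fewer=True)
    n_splits = int(min(cv_folds, counts.min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    press = 0.0
    for train_idx, test_idx in cv.split(X, y):
        fold = fit_pls(X[train_idx], y[train_idx], n_components,
                       allow_fewer=True)
        pred = fold.predict(X[test_idx])
        press += float(((y[test_idx] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    comp1 = model.vip_for(min(1, model.n_components))
    return DAResult(model=model, q2=q2, component1_vip=comp1, classes=classes)


def permutation_test(X, labels, n_components: int = 2, n_perm: int = 199,
                     seed: int = 0) -> float:
    """Permutation p-value for the class separation of a PLS-DA model.

    The statistic is the training R2 of the class-coded PLS model; labels
    are permuted ``n_perm`` times and the add-one estimator
    ``p = (1 + #{permuted >= observed}) / (1 + n_perm)`` is returned, so the
    smallest achievable p-value is ``1 / (1 + n_perm)`` (5e-4 at 1999
    permutations).
    """
    n_perm = int(n_perm)
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 (p cannot fall below 0.05)")
    X = np.asarray(X, dtype=float)
    y, _ = _code_labels(labels)
    observed = fit_pls(X, y, n_components, allow_fewer=True).r2
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        stat = fit_pls(X, perm, n_components, allow_fewer=True).r2
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def pearson_predictability(observed, predicted):
    """Pearson r and two-sided p between observed and predicted values.

    Returns (nan, nan) when fewer than 3 pairs or either vector is constant.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape[0] < 3:
        return float("nan"), float("nan")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(observed, predicted)
    return float(r), float(p)
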