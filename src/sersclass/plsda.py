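"""PLS-DA from scratch.

Partial least squares regression of a {0,1}-coded class response onto the
spectra (PLS1, NIPALS deflation), used as a classifier with a score
threshold. For a univariate response the NIPALS weight vector is closed form
per component (w proportional to X'y), so no inner iteration is needed.
Includes patient-grouped K-fold cross-validation of the RMSE-vs-components
curve, first-local-minimum component selection, and variable importance in
projection (VIP) scores.

Predictors are only mean-centered on the training set: spectra arriving here
are already SNV-normalized per spectrum, so no column autoscaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSConfig",
    "PLSDAModel",
    "RMSECurve",
    "fit_pls",
    "predict_scores",
    "classify",
    "cv_rmse",
    "select_n_lv",
    "vip_scores",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PLSConfig:
    """Classifier settings used by the resampling protocol: number of CV
    folds, the largest candidate latent-variable count, and the decision
    threshold on the continuous score."""

    K: int = 10
    max_lv: int = 15
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.max_lv < 1:
            raise ValueError(f"max_lv must be >= 1, got {self.max_lv}")


@dataclass(eq=False)
class PLSDAModel:
    """Fitted PLS1 discriminant model.

    ``W`` holds the unit-norm NIPALS weights, ``P_load`` the predictor
    loadings, ``q`` the response loadings and ``R = W (P'W)^-1`` the basis
    that maps centered predictors directly to scores; ``b = R q`` are the
    regression coefficients. Prediction via ``b`` and via sequential LV
    reconstruction agree to floating-point accuracy.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P_load: np.ndarray
    q: np.ndarray
    R: np.ndarray
    b: np.ndarray
    class_codes: dict[str, int] = field(default_factory=lambda: {"negative": 0, "positive": 1})


@dataclass(eq=False)
class RMSECurve:
    """Cross-validated RMSE per candidate LV count 1..max_lv."""

    rmse: np.ndarray

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=float)
        if self.rmse.ndim != 1:
            raise ValueError("RMSECurve.rmse must be a vector")
        if np.any(self.rmse < 0):
            raise ValueError("RMSECurve.rmse must be nonnegative")


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS for univariate y: returns (W, P, q, T)."""
    n, p = Xc.shape
    X = Xc.copy()
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    for a in range(n_lv):
        w = X.T @ yc
        norm_w = float(np.linalg.norm(w))
        if norm_w < _EPS:
            raise ValueError(
                f"n_lv too large: response covariance exhausted after {a} latent variables"
            )
        w /= norm_w
        t = X @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ValueError(
                f"n_lv too large: predictor variance exhausted after {a} latent variables"
            )
        p_a = X.T @ t / tt
        q[a] = float(yc @ t) / tt
        X -= np.outer(t, p_a)
        W[:, a], P[:, a], T[:, a] = w, p_a, t
    return W, P, q, T


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    class_codes: dict[str, int] | None = None,
) -> PLSDAModel:
    """Fit a PLS1 model of the 0/1 response on mean-centered predictors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, min(rows-1, predictors)] = [1, {min(n - 1, p)}], got {n_lv}")
    for code in (0.0, 1.0):
        if int(np.sum(y == code)) < 2:
            raise ValueError(f"need at least 2 samples of class {int(code)}, got {int(np.sum(y == code))}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals(X - x_mean, y - y_mean, n_lv)
    R = W @ np.linalg.inv(P.T @ W)
    b = R @ q
    return PLSDAModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P_load=P,
        q=q,
        R=R,
        b=b,
        class_codes=dict(class_codes) if class_codes else {"negative": 0, "positive": 1},
    )


def predict_scores(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous response per row: (x - x_mean) . b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.b.shape[0]:
        raise ValueError(f"model expects {model.b.shape[0]} predictors, got {X.shape[1]}")
    return (X - model.x_mean) @ model.b + model.y_mean


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from continuous scores: 1 iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def _grouped_folds(patient_ids: np.ndarray, y: np.ndarray, K: int, rng: np.random.Generator):
    """Partition patients (not spectra) into K folds, stratified by class."""
    patient_ids = np.asarray(patient_ids, dtype=object)
    uniq, first = np.unique(patient_ids, return_index=True)
    if uniq.size < K:
        raise ValueError(f"need at least K={K} patients, got {uniq.size}")
    fold_of_patient: dict[object, int] = {}
    counter = 0
    for cls in np.unique(y[first]):
        members = uniq[y[first] == cls].copy()
        rng.shuffle(members)
        for pid in members:
            fold_of_patient[pid] = counter % K
            counter += 1
    folds = np.array([fold_of_patient[pid] for pid in patient_ids])
    return [np.where(folds == k)[0] for k in range(K) if np.any(folds == k)]


def cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    max_lv: int = 15,
    K: int = 10,
    rng: np.random.Generator | None = None,
) -> RMSECurve:
    """Patient-grouped K-fold CV curve of held-out RMSE vs LV count.

    Folds partition patients, never spectra of one patient across folds.
    Each fold is fitted once at the largest feasible LV count; predictions
    for smaller counts come from truncating the component sequence, so the
    pooled squared errors per count are identical to per-count refits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    patient_ids = np.asarray(patient_ids, dtype=object)
    if rng is None:
        rng = np.random.default_rng()
    folds = _grouped_folds(patient_ids, y, K, rng)
    lv_cap = min(max_lv, X.shape[1], min(X.shape[0] - len(f) for f in folds) - 1)
    if lv_cap < 1:
        raise ValueError("not enough training samples per fold for even one latent variable")
    sq_err = np.zeros(lv_cap)
    for test_idx in folds:
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        x_mean, y_mean = Xtr.mean(axis=0), float(ytr.mean())
        W, P, q, _ = _nipals(Xtr - x_mean, ytr - y_mean, lv_cap)
        R = W @ np.linalg.inv(P.T @ W)
        scores_test = (X[test_idx] - x_mean) @ R  # n_test x lv_cap
        preds = y_mean + np.cumsum(scores_test * q, axis=1)  # column a = a+1 LVs
        sq_err += np.sum((preds - y[test_idx, None]) ** 2, axis=0)
    return RMSECurve(rmse=np.sqrt(sq_err / X.shape[0]))


def select_n_lv(curve: RMSECurve) -> int:
    """First local minimum of the CV RMSE curve (1-based LV count).

    The smallest i with rmse[i] < rmse[i-1] and rmse[i] <= rmse[i+1] (last
    point needs no right neighbor; the first point qualifies when
    rmse[1] <= rmse[2]). A monotone nonincreasing curve therefore yields its
    global minimum, the last point.
    """
    r = curve.rmse
    n = r.size
    if n == 0:
        raise ValueError("empty RMSE curve")
    for i in range(n):
        left_ok = i == 0 or r[i] < r[i - 1]
        right_ok = i == n - 1 or r[i] <= r[i + 1]
        if left_ok and right_ok:
            return i + 1
    return int(np.argmin(r)) + 1  # unreachable for finite curves; defensive


def vip_scores(model: PLSDAModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Variable importance in projection on the model's training data.

    VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) with SSY_a the
    response sum of squares explained by component a (weights are unit
    norm). The squared VIPs average to exactly 1.
    """
    X = np.asarray(X, dtype=float)
    T = (X - model.x_mean) @ model.R
    ssy = model.q**2 * np.sum(T**2, axis=0)
    total = float(ssy.sum())
    if total <= _EPS:
        raise ValueError("vip_scores: model explains no response variance")
    p = model.W.shape[0]
    return np.sqrt(p * (model.W**2 @ ssy) / total)
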