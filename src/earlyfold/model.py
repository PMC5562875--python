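"""Class-weighted RBF-SVM, Platt probability calibration, thresholding.

The classifier is a maximum-margin kernel machine with a Gaussian (RBF)
kernel, with class weights compensating the roughly 1:6 imbalance between
early-folding and other residues. Calibrated probabilities come from Platt
scaling of the signed hyperplane distance *s*:

    p(early | s) = 1 / (1 + exp(A·s + B)),   A < 0

and the binary call is ``p >= tau`` (inclusive), default ``tau = 0.163``.

Defaults ``C = 100``, ``gamma = 0.04`` and ``tau = 0.163`` are the values
used throughout this package's evaluation protocol.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    DEFAULT_PREDICTOR_HALF_WIDTH,
    FEATURE_DIM,
    ProfilePredictor,
)

DEFAULT_C = 100.0
DEFAULT_GAMMA = 0.04
DEFAULT_THRESHOLD = 0.163

__all__ = [
    "DEFAULT_C",
    "DEFAULT_GAMMA",
    "DEFAULT_THRESHOLD",
    "EFoldModel",
    "train",
    "platt_calibrate",
    "platt_sigmoid",
    "calibrate",
    "decision_function",
    "predict_proba",
    "classify",
    "save_model",
    "load_model",
]


@dataclass
class EFoldModel:
    """A fitted kernel classifier plus its calibration and threshold.

    The decision function is stored explicitly (support vectors, dual
    coefficients, intercept) so that models persist to plain JSON and load
    without unpickling anything.
    """

    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    class_weight: str | Mapping[int, float] = "balanced"
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0
    A: float | None = None  # Platt slope (negative for positive orientation)
    B: float | None = None  # Platt offset
    tau: float = DEFAULT_THRESHOLD
    n_features: int = FEATURE_DIM

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"threshold tau={self.tau} outside [0, 1]")

    @property
    def is_fitted(self) -> bool:
        return self.support_vectors is not None

    @property
    def is_calibrated(self) -> bool:
        return self.A is not None and self.B is not None


def _check_features(X: np.ndarray, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"expected {n_features} features per row, got {X.shape[1]}"
        )
    return X


def train(
    X: np.ndarray,
    y: Sequence[int],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    class_weight: str | Mapping[int, float] = "balanced",
    tau: float = DEFAULT_THRESHOLD,
) -> EFoldModel:
    """Fit the class-weighted RBF-SVM; returns an uncalibrated model.

    ``class_weight='balanced'`` weights each class inversely to its
    frequency; an explicit ``{0: w0, 1: w1}`` map is also accepted.
    """
    X = _check_features(X)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    svc = SVC(
        C=C,
        gamma=gamma,
        kernel="rbf",
        class_weight=class_weight,
        cache_size=500,
        tol=1e-6,  # tight optimum makes the fit row-order invariant
    )
    svc.fit(X, y)
    # classes_ is [0, 1]; positive decision values favour class 1
    return EFoldModel(
        C=C,
        gamma=gamma,
        class_weight=class_weight,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        tau=tau,
        n_features=X.shape[1],
    )


def decision_function(model: EFoldModel, X: np.ndarray) -> np.ndarray:
    """Signed hyperplane distance; positive side is the early-folding class."""
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    X = _check_features(X, model.n_features)
    K = rbf_kernel(X, model.support_vectors, gamma=model.gamma)
    return K @ model.dual_coef + model.intercept


def platt_sigmoid(scores: np.ndarray, A: float, B: float) -> np.ndarray:
    """p = 1 / (1 + exp(A·s + B)), computed overflow-safely."""
    z = A * np.asarray(scores, dtype=float) + B
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out


def platt_calibrate(
    decision_scores: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Fit the Platt sigmoid ``p = 1/(1+exp(A·s+B))`` by Newton iteration.

    Maximizes the regularized binomial likelihood with the standard
    smoothed targets ``t+ = (N+ + 1)/(N+ + 2)`` and ``t− = 1/(N− + 2)``
    instead of raw 0/1 labels, which keeps the fit finite for separable
    scores. Raises on degenerate input where every score is identical.
    """
    s = np.asarray(decision_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration needs both classes")
    if np.ptp(s) == 0:
        raise ValueError("all decision scores identical; cannot calibrate")

    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12  # Levenberg–Marquardt floor on the Hessian

    def objective(a: float, b: float) -> float:
        z = a * s + b
        # -sum[t*log p + (1-t)*log(1-p)] in a form stable for large |z|
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    f_old = objective(A, B)
    for _ in range(max_iter):
        p = platt_sigmoid(s, A, B)
        d1 = t - p  # dF/dz for F = sum[t*z + log(1+exp(-z))], z = A*s + B
        d2 = p * (1.0 - p)
        g_a = float(np.dot(s, d1))
        g_b = float(np.sum(d1))
        if abs(g_a) < tol and abs(g_b) < tol:
            break
        h_aa = float(np.dot(s * s, d2)) + sigma
        h_bb = float(np.sum(d2)) + sigma
        h_ab = float(np.dot(s, d2))
        det = h_aa * h_bb - h_ab * h_ab
        dA = -(h_bb * g_a - h_ab * g_b) / det
        dB = -(h_aa * g_b - h_ab * g_a) / det
        # backtracking line search on the Newton direction
        step = 1.0
        gd = g_a * dA + g_b * dB
        while step >= 1e-10:
            f_new = objective(A + step * dA, B + step * dB)
            if f_new < f_old + 1e-4 * step * gd:
                A, B = A + step * dA, B + step * dB
                f_old = f_new
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def calibrate(
    model: EFoldModel,
    X: np.ndarray,
    y: Sequence[int],
    cv: int | None = 3,
    random_state: int = 0,
) -> tuple[EFoldModel, np.ndarray]:
    """Fit Platt coefficients for ``model`` on labelled data.

    With ``cv`` (default 3), decision scores for calibration come from an
    internal stratified cross-validation — each score is produced by a
    classifier that never saw that row — which avoids the optimistic
    calibration a training-set fit gives with separable kernels. ``cv=None``
    calibrates directly on the training-set decision values.

    Returns the calibrated model and the calibration-time probabilities of
    the training rows (useful for fitting a decision threshold without
    touching held-out data).
    """
    X = _check_features(X, model.n_features)
    y = np.asarray(y, dtype=int)
    if cv is None:
        scores = decision_function(model, X)
    else:
        scores = np.empty(len(y))
        splitter = StratifiedKFold(
            n_splits=cv, shuffle=True, random_state=random_state
        )
        for tr, te in splitter.split(X, y):
            sub = train(
                X[tr],
                y[tr],
                C=model.C,
                gamma=model.gamma,
                class_weight=model.class_weight,
            )
            scores[te] = decision_function(sub, X[te])
    A, B = platt_calibrate(scores, y)
    if A >= 0:
        warnings.warn(
            "Platt slope is non-negative: decision values are anti-correlated "
            "with the positive class",
            stacklevel=2,
        )
    calibrated = replace(model, A=A, B=B)
    return calibrated, platt_sigmoid(scores, A, B)


def predict_proba(model: EFoldModel, X: np.ndarray) -> np.ndarray:
    """Calibrated early-folding probability for each feature row."""
    if not model.is_calibrated:
        raise ValueError("model is not calibrated; run calibrate() first")
    return platt_sigmoid(decision_function(model, X), model.A, model.B)


def classify(
    probabilities: Sequence[float], tau: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Binary calls: 1 iff probability >= tau (threshold inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau={tau} outside [0, 1]")
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities outside [0, 1]")
    return (p >= tau).astype(np.int8)


MODEL_FORMAT_VERSION = 1


def save_model(
    model: EFoldModel,
    path: str | Path,
    profile_predictor: ProfilePredictor | None = None,
) -> None:
    """Persist a model (and optionally its profile predictor) as JSON."""
    if not model.is_fitted:
        raise ValueError("refusing to save an unfitted model")
    doc = {
        "format": "earlyfold-model",
        "version": MODEL_FORMAT_VERSION,
        "C": model.C,
        "gamma": model.gamma,
        "class_weight": (
            model.class_weight
            if isinstance(model.class_weight, str)
            else {str(k): v for k, v in model.class_weight.items()}
        ),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "platt_A": model.A,
        "platt_B": model.B,
        "tau": model.tau,
        "n_features": model.n_features,
    }
    if profile_predictor is not None:
        doc["profile_predictor"] = {
            "half_width": profile_predictor.half_width,
            "channels": list(profile_predictor.channels),
            "coef": profile_predictor.coef.tolist(),
            "intercept": profile_predictor.intercept.tolist(),
        }
    Path(path).write_text(json.dumps(doc))


def load_model(
    path: str | Path,
) -> tuple[EFoldModel, ProfilePredictor | None]:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "earlyfold-model":
        raise ValueError(f"{path} is not an earlyfold model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {doc.get('version')}"
        )
    cw = doc["class_weight"]
    if isinstance(cw, dict):
        cw = {int(k): float(v) for k, v in cw.items()}
    model = EFoldModel(
        C=doc["C"],
        gamma=doc["gamma"],
        class_weight=cw,
        support_vectors=np.asarray(doc["support_vectors"], float),
        dual_coef=np.asarray(doc["dual_coef"], float),
        intercept=doc["intercept"],
        A=doc["platt_A"],
        B=doc["platt_B"],
        tau=doc["tau"],
        n_features=doc["n_features"],
    )
    predictor = None
    if "profile_predictor" in doc:
        pp = doc["profile_predictor"]
        predictor = ProfilePredictor(
            half_width=pp.get("half_width", DEFAULT_PREDICTOR_HALF_WIDTH),
            coef=np.asarray(pp["coef"], float),
            intercept=np.asarray(pp["intercept"], float),
            channels=tuple(pp["channels"]),
        )
    return model, predictor
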