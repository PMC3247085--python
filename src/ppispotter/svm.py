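"""Weighted linear soft-margin SVM and probability calibration.

The classifier minimizes

    1/2 ||w||^2 + C * sum_i s_i * H1(y_i (w.x_i + b)),    H1(t) = max(0, 1-t)

over (w, b) for per-sample weights s_i >= 0.  Decision values are mapped
to class probabilities through a one-parameter sigmoid

    P(y=+1 | x) = 1 / (1 + exp(A * f(x)/||w||)),    A < 0,

whose intercept is eliminated by pinning probability 0.5 to the decision
boundary; the slope A is fitted by maximum likelihood with Platt's
smoothed targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

#: slope bounds keep probabilities finite and orientation fixed
A_MIN, A_MAX = -50.0, -1e-6

_WEIGHT_EPS = 1e-12


@dataclass
class LinearModel:
    """A trained linear decision function f(x) = w.x + b."""

    w: np.ndarray
    b: float
    C: float

    @property
    def w_norm(self) -> float:
        return float(np.linalg.norm(self.w))


@dataclass
class Calibration:
    """Fitted sigmoid slope; the intercept is identically zero so that
    points on the decision boundary get probability exactly 0.5."""

    A: float
    B: float = 0.0


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    sample_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1_000_000,
) -> LinearModel:
    """Fit the weighted linear soft-margin SVM.

    Samples with (near-)zero weight are dropped before solving; both
    classes must remain represented.  The solver is deterministic given
    its inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if C <= 0:
        raise ValueError("C must be positive")
    if sample_weights is None:
        sample_weights = np.ones(len(y))
    sample_weights = np.asarray(sample_weights, dtype=float)
    keep = sample_weights > _WEIGHT_EPS
    Xk, yk, sk = X[keep], y[keep], sample_weights[keep]
    if len(np.unique(yk)) < 2:
        raise ValueError("training data must contain both classes")
    # SVC's effective per-sample penalty is C * sample_weight, which is
    # exactly the weighted hinge objective above.  max_iter bounds SMO on
    # degenerate duals (duplicated points with opposite labels), where it
    # can cycle below its achievable precision.
    svc = SVC(kernel="linear", C=C, tol=tol, cache_size=64, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Xk, yk, sample_weight=sk)
    w = svc.coef_.ravel().astype(float)
    # sklearn orients coef_ toward its classes_[1]; flip if that is -1
    if svc.classes_[1] < 0:
        w, b = -w, -float(svc.intercept_[0])
    else:
        b = float(svc.intercept_[0])
    return LinearModel(w=w, b=b, C=float(C))


def decision_value(model: LinearModel, x: np.ndarray) -> float | np.ndarray:
    """f(x) = w.x + b; accepts a single vector or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.w.shape[0]:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} != {model.w.shape[0]}")
    out = x @ model.w + model.b
    return float(out) if out.ndim == 0 else out


def normalized_score(model: LinearModel, x: np.ndarray) -> float | np.ndarray:
    """Margin-normalized decision value f(x)/||w||: the signed geometric
    distance to the hyperplane, invariant to rescaling of (w, b)."""
    nw = model.w_norm
    if nw == 0:
        raise ValueError("zero weight vector has no margin")
    return decision_value(model, x) / nw


def fit_calibration(model: LinearModel, X: np.ndarray, y: np.ndarray) -> Calibration:
    """Fit the sigmoid slope A by maximum likelihood.

    Targets are Platt-smoothed: (N+ + 1)/(N+ + 2) for positives and
    1/(N- + 2) for negatives, which regularizes the fit on separable
    data; A is bounded in [-50, -1e-6].
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration requires both classes")
    s = np.asarray(normalized_score(model, X), dtype=float)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    t = np.where(y > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(A: float) -> float:
        p = expit(-A * s)
        p = np.clip(p, 1e-15, 1 - 1e-15)
        return -float(np.sum(t * np.log(p) + (1 - t) * np.log(1 - p)))

    res = minimize_scalar(nll, bounds=(A_MIN, A_MAX), method="bounded",
                          options={"xatol": 1e-10})
    return Calibration(A=float(np.clip(res.x, A_MIN, A_MAX)))


def class_probability(
    model: LinearModel, calib: Calibration, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(P+, P-) for one vector or a matrix of rows; P+ + P- = 1 exactly."""
    s = np.asarray(normalized_score(model, x), dtype=float)
    p_pos = expit(-calib.A * s)
    return p_pos, 1.0 - p_pos


def save_model(model: LinearModel, calib: Calibration | None, path: str | Path) -> None:
    doc = {"w": model.w.tolist(), "b": model.b, "C": model.C,
           "A": calib.A if calib is not None else None}
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[LinearModel, Calibration | None]:
    doc = json.loads(Path(path).read_text())
    model = LinearModel(w=np.asarray(doc["w"], dtype=float), b=doc["b"], C=doc["C"])
    calib = Calibration(A=doc["A"]) if doc.get("A") is not None else None
    return model, calib
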