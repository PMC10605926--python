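"""Sparse soft-margin SVM primitives.

The model is the linear classifier sign(phi' theta + theta0) fit by

    min_{theta, theta0}  sum_i max(0, 1 - l_i (phi_i' theta + theta0))
                         + 0.5 * psi * ||theta||_2^2 + rho * ||theta||_1

The bias theta0 is never penalised, and sign(0) predicts +1. Alongside the
objective this module provides the two proximal operators the splitting
solver needs (elastic-net prox for the regulariser, clipped shift for the
hinge conjugate) and the stacked margin operator A with rows l_i [phi_i', 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .datasets import Dataset

__all__ = [
    "Classifier", "Hyperparams", "hinge_losses", "objective",
    "hyperparams_from_c_eps", "predict_accuracy", "prox_regularizer",
    "prox_hinge_conjugate", "build_margin_operator",
    "save_classifier", "load_classifier",
]


@dataclass
class Classifier:
    theta: np.ndarray
    theta0: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.theta0 = float(self.theta0)
        if not (np.isfinite(self.theta).all() and np.isfinite(self.theta0)):
            raise ValueError("classifier parameters must be finite")

    @property
    def d(self) -> int:
        return self.theta.size

    def nonzero_support(self, tol: float = 1e-8) -> np.ndarray:
        return np.flatnonzero(np.abs(self.theta) > tol)


@dataclass(frozen=True)
class Hyperparams:
    """psi: ridge coefficient, rho: L1 coefficient (both >= 0)."""

    psi: float
    rho: float

    def __post_init__(self) -> None:
        if self.psi < 0 or self.rho < 0:
            raise ValueError("penalty coefficients must be nonnegative")


def _margins(clf: Classifier, data: Dataset) -> np.ndarray:
    if data.n_features != clf.d:
        raise ValueError(
            f"dimension mismatch: classifier has d={clf.d}, "
            f"data has d={data.n_features}")
    return data.labels * (data.features @ clf.theta + clf.theta0)


def hinge_losses(clf: Classifier, data: Dataset) -> np.ndarray:
    """Per-sample hinge losses max(0, 1 - l_i (phi_i' theta + theta0))."""
    return np.maximum(0.0, 1.0 - _margins(clf, data))


def objective(clf: Classifier, data: Dataset, hp: Hyperparams) -> float:
    """Hinge sum + 0.5*psi*||theta||^2 + rho*||theta||_1 (bias unpenalised)."""
    return float(
        hinge_losses(clf, data).sum()
        + 0.5 * hp.psi * float(clf.theta @ clf.theta)
        + hp.rho * float(np.abs(clf.theta).sum())
    )


def hyperparams_from_c_eps(c: float, eps: float) -> Hyperparams:
    """Convert the (c, eps) form  0.5||theta||^2 + c*sum zeta + eps*||theta||_1
    to the (psi, rho) form by dividing through by c; minimisers coincide."""
    if c <= 0:
        raise ValueError("c must be positive")
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    return Hyperparams(psi=1.0 / c, rho=eps / c)


def predict_accuracy(clf: Classifier, data: Dataset
                     ) -> tuple[np.ndarray, float]:
    """Predicted +/-1 labels (sign(0) -> +1) and the matching fraction."""
    if data.n_samples == 0:
        raise ValueError("cannot predict on an empty dataset")
    scores = data.features @ clf.theta + clf.theta0
    preds = np.where(scores >= 0, 1, -1)
    return preds, float(np.mean(preds == data.labels))


def soft_threshold(u: np.ndarray, t: float) -> np.ndarray:
    return np.sign(u) * np.maximum(np.abs(u) - t, 0.0)


def prox_regularizer(u: np.ndarray, tau: float, hp: Hyperparams) -> np.ndarray:
    """Prox of tau * (0.5*psi*||.||^2 + rho*||.||_1) on the weight slots.

    The last coordinate of ``u`` is the bias slot and passes through
    unchanged. Closed form: soft_threshold(u, tau*rho) / (1 + tau*psi).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = np.asarray(u, dtype=float)
    out = u.copy()
    out[:-1] = soft_threshold(u[:-1], tau * hp.rho) / (1.0 + tau * hp.psi)
    return out


def prox_hinge_conjugate(v: np.ndarray,
                         sigma: Union[float, np.ndarray]) -> np.ndarray:
    """Prox of sigma * h* where h(y) = max(0, 1 - y).

    The conjugate is h*(u) = u on [-1, 0] and +inf elsewhere, so the prox is
    the clipped shift clip(v - sigma, -1, 0). ``sigma`` may be a vector for
    per-coordinate scaling (sample weights).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return np.clip(np.asarray(v, dtype=float) - sigma, -1.0, 0.0)


def build_margin_operator(data: Dataset) -> np.ndarray:
    """n x (d+1) matrix A with row i = l_i * [phi_i', 1].

    For x = (theta, theta0), (A x)_i is the margin l_i(phi_i' theta + theta0).
    """
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    ones = np.ones((data.n_samples, 1))
    return data.labels[:, None] * np.hstack([data.features, ones])


def save_classifier(clf: Classifier, path, feature_names=None) -> None:
    Path(path).write_text(json.dumps({
        "theta": clf.theta.tolist(),
        "theta0": clf.theta0,
        "feature_names": list(feature_names) if feature_names else None,
    }))


def load_classifier(path) -> tuple[Classifier, Optional[list[str]]]:
    obj = json.loads(Path(path).read_text())
    return Classifier(np.array(obj["theta"]), obj["theta0"]), obj["feature_names"]
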