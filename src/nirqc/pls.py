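"""Partial least squares regression (PLS1) with latent-variable selection.

The calibration engine of the pipeline: a NIPALS decomposition of the
mean-centered absorbance matrix against a single reference indicator.
For PLS1 each component is closed-form (no inner iteration): the weight is
the covariance direction w = X'y / ||X'y||, scores t = Xw, loadings
p = X't/t't, q = y't/t't, then X and y are deflated.  The compacted
regression vector for h components is B_h = W (P'W)^{-1} q, accumulated
incrementally so one decomposition yields the coefficient path for every
h = 1..max_lvs — which is what makes leave-one-out RMSECV over the whole
latent-variable grid affordable.

Model complexity (the number of latent variables, "LVs") is chosen by the
minimum leave-one-out cross-validated RMSECV, ties broken toward the
smaller model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PLSModel",
    "fit_pls",
    "predict",
    "coefficient_paths",
    "cv_rmsecv_curve",
    "select_lvs_loocv",
    "cv_rmsecv",
]

_NIPALS_TOL = 1e-12  # squared-norm floor below which deflation has exhausted X'y


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model compacted to an affine predictor."""

    n_lvs: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # one per input variable
    indicator: str = ""
    variable_indices: tuple[int, ...] | None = None
    pretreatment: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_mean", np.asarray(self.x_mean, dtype=float))
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite PLS coefficients")

    @property
    def n_vars(self) -> int:
        return self.coefficients.size

    def to_json(self) -> str:
        payload = {
            "n_lvs": self.n_lvs,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coefficients": self.coefficients.tolist(),
            "indicator": self.indicator,
            "variable_indices": None if self.variable_indices is None else list(self.variable_indices),
            "pretreatment": self.pretreatment,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        vi = d["variable_indices"]
        return cls(
            n_lvs=d["n_lvs"],
            x_mean=np.array(d["x_mean"]),
            y_mean=d["y_mean"],
            coefficients=np.array(d["coefficients"]),
            indicator=d["indicator"],
            variable_indices=None if vi is None else tuple(vi),
            pretreatment=d["pretreatment"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_json(Path(path).read_text())


def coefficient_paths(X: np.ndarray, y: np.ndarray, max_lvs: int) -> tuple[np.ndarray, np.ndarray, float]:
    """NIPALS coefficient paths: B[:, h-1] is the regression vector with h LVs.

    Returns ``(B, x_mean, y_mean)``; prediction with h components is
    ``(X - x_mean) @ B[:, h-1] + y_mean``.  If deflation exhausts the
    covariance before ``max_lvs`` components, later columns repeat the last
    attainable one (the model stops improving, it never degrades).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of samples")
    if n < 2:
        raise ValueError("need at least 2 calibration samples")
    max_lvs = int(max_lvs)
    if max_lvs < 1:
        raise ValueError("max_lvs must be >= 1")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    B = np.zeros((p, max_lvs))
    W = np.zeros((p, max_lvs))
    P = np.zeros((p, max_lvs))
    R = np.zeros((p, max_lvs))  # R = W (P'W)^{-1}, built incrementally
    b = np.zeros(p)
    for h in range(max_lvs):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn**2 <= _NIPALS_TOL:
            B[:, h:] = b[:, None]
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _NIPALS_TOL:
            B[:, h:] = b[:, None]
            break
        pvec = (Xc.T @ t) / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pvec)
        yc = yc - q * t
        W[:, h] = w
        P[:, h] = pvec
        r = w - R[:, :h] @ (P[:, :h].T @ w)
        R[:, h] = r
        b = b + q * r
        B[:, h] = b
    return B, x_mean, y_mean


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lvs: int,
    indicator: str = "",
    variable_indices: Sequence[int] | None = None,
    pretreatment: str = "raw",
) -> PLSModel:
    """Fit a PLS1 model with exactly ``n_lvs`` latent variables.

    A constant response deflates to nothing in the first component; the
    model then has a zero coefficient vector and predicts the mean
    everywhere (a warning is emitted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    bound = min(n - 1, p)
    if not 1 <= n_lvs <= bound:
        raise ValueError(f"n_lvs={n_lvs} outside [1, min(n-1, p)] = [1, {bound}]")
    if np.ptp(y) == 0:
        warnings.warn("constant y: PLS model degenerates to the mean predictor", stacklevel=2)
    B, x_mean, y_mean = coefficient_paths(X, y, n_lvs)
    return PLSModel(
        n_lvs=n_lvs,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=B[:, n_lvs - 1],
        indicator=indicator,
        variable_indices=None if variable_indices is None else tuple(int(i) for i in variable_indices),
        pretreatment=pretreatment,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Affine prediction: (X - x_mean) @ b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_vars:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.n_vars}")
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def _fold_indices(n: int, k: int) -> list[np.ndarray]:
    """Contiguous, near-equal CV folds (deterministic; k == n is LOO)."""
    return [idx for idx in np.array_split(np.arange(n), k) if idx.size]


def cv_rmsecv_curve(X: np.ndarray, y: np.ndarray, max_lvs: int, cv: int) -> np.ndarray:
    """RMSECV for h = 1..max_lvs under k-fold CV (cv == n gives leave-one-out)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cv = min(int(cv), n)
    if cv < 2:
        raise ValueError("need at least 2 CV folds")
    max_lvs = min(int(max_lvs), min(n - len(max(_fold_indices(n, cv), key=len)) - 1, p))
    max_lvs = max(max_lvs, 1)
    press = np.zeros(max_lvs)
    for test in _fold_indices(n, cv):
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        B, xm, ym = coefficient_paths(X[train], y[train], max_lvs)
        pred = (X[test] - xm) @ B + ym  # (n_test, max_lvs)
        press += ((pred - y[test][:, None]) ** 2).sum(axis=0)
    return np.sqrt(press / n)


def select_lvs_loocv(X: np.ndarray, y: np.ndarray, max_lvs: int = 15) -> tuple[int, np.ndarray]:
    """Latent-variable count by minimum leave-one-out RMSECV (tie -> smaller h)."""
    n, p = np.asarray(X).shape
    if n < 3:
        raise ValueError("leave-one-out LV selection needs at least 3 samples")
    bound = min(n - 2, p)  # LOO training sets have n-1 rows
    if max_lvs > bound:
        warnings.warn(f"max_lvs={max_lvs} clipped to {bound}", stacklevel=2)
        max_lvs = bound
    curve = cv_rmsecv_curve(X, y, max_lvs, cv=n)
    best = int(np.argmin(curve)) + 1
    return best, curve


def cv_rmsecv(X: np.ndarray, y: np.ndarray, max_lvs: int, cv: int) -> tuple[float, int]:
    """Minimum of the RMSECV curve and its LV count (tie -> smaller h)."""
    curve = cv_rmsecv_curve(X, y, max_lvs, cv)
    best = int(np.argmin(curve))
    return float(curve[best]), best + 1
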