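"""Model evaluation: R / RMSE / RSE, RPD, Wilcoxon rank-sum, distance correlation.

Conventions (fixed by recomputing published external-validation tables for
this formulation from their printed reference/predicted pairs):

* R is the residual-based coefficient ``sqrt(max(0, 1 - SSres/SStot))`` —
  not Pearson's r — applied uniformly as Rc/Rp/Rv;
* RSE (relative standard error, percent) normalizes the residual norm by
  the reference-value norm: ``100 * sqrt(SSres / sum(y^2))``;
* RMSE is ``sqrt(SSres / n)``;
* RPD is the prediction-set reference standard deviation (n-1 denominator)
  divided by RMSEP; RPD > 3 flags a calibration fit for routine use.

The Wilcoxon rank-sum test compares reference and predicted values of the
external-validation set: a large two-sided p (> 0.05) supports "no
systematic difference".  Distance correlation quantifies (possibly
non-linear) dependence between the bioactivity endpoint and each analyte,
with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "regression_metrics",
    "rpd",
    "RPD_THRESHOLD",
    "wilcoxon_rank_sum",
    "distance_correlation",
]

RPD_THRESHOLD = 3.0


@dataclass(frozen=True)
class MetricsReport:
    """Metric bundle for one model on one sample set."""

    set_label: str  # calibration | prediction | validation
    n: int
    R: float
    RMSE: float
    RSE: float  # percent
    RPD: float | None = None  # prediction set only
    RMSECV: float | None = None
    LVs: int | None = None
    wilcoxon_p: float | None = None  # validation only

    def as_dict(self) -> dict[str, object]:
        return {k: v for k, v in self.__dict__.items()}


def regression_metrics(y_ref: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """R, RMSE and RSE (%) of predictions against reference values."""
    y = np.asarray(y_ref, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yh.size:
        raise ValueError("reference and predicted vectors differ in length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_res = float(np.sum((yh - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant reference values: R is undefined")
    ss_y = float(np.sum(y**2))
    if ss_y == 0:
        raise ValueError("all-zero reference values: RSE is undefined")
    return {
        "R": float(np.sqrt(max(0.0, 1.0 - ss_res / ss_tot))),
        "RMSE": float(np.sqrt(ss_res / y.size)),
        "RSE": float(100.0 * np.sqrt(ss_res / ss_y)),
    }


def rpd(y_ref_prediction: np.ndarray, rmsep: float) -> dict[str, object]:
    """Residual predictive deviation = sd(prediction-set reference)/RMSEP.

    Returns the value plus a pass flag at the conventional threshold of 3.
    """
    y = np.asarray(y_ref_prediction, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 prediction-set samples")
    if not rmsep > 0:
        raise ValueError("RMSEP must be positive")
    value = float(np.std(y, ddof=1) / rmsep)
    return {"RPD": value, "passes": value > RPD_THRESHOLD}


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum: (rank-sum statistic of ``a``, two-sided p).

    Exact null distribution when both samples have <= 20 observations and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum of a
    return w, float(min(res.pvalue, 1.0))


def _dcov_sq(A: np.ndarray, B: np.ndarray) -> float:
    return float((A * B).mean())


def _double_center(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def distance_correlation(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Distance correlation between two vectors, optional permutation p.

    Standard double-centered distance covariance / variance ratio.  With
    ``n_perm`` > 0 a p-value is estimated by permuting ``b`` (add-one
    smoothed).  Constant input gives dCor 0.
    """
    import warnings

    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors differ in length")
    if a.size < 4:
        raise ValueError("distance correlation needs at least 4 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input: distance correlation set to 0", stacklevel=2)
        return 0.0, (1.0 if n_perm else None)

    A = _double_center(a)
    B = _double_center(b)
    dvar_a = _dcov_sq(A, A)
    dvar_b = _dcov_sq(B, B)
    dcor = float(np.sqrt(max(0.0, _dcov_sq(A, B)) / np.sqrt(dvar_a * dvar_b)))
    if n_perm <= 0:
        return dcor, None

    rng = np.random.default_rng(seed)
    stat = _dcov_sq(A, B)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(b.size)
        if _dcov_sq(A, B[np.ix_(perm, perm)]) >= stat:
            count += 1
    return dcor, (count + 1) / (n_perm + 1)
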