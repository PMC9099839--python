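"""Wavenumber selection: synergy-interval PLS, CARS, and random frog.

All three return a :class:`VariableSubset` — sorted unique 0-based positions
in the descending wavenumber grid — chosen by minimum cross-validated
RMSECV, together with the winning hyperparameters.

* SIPLS divides the grid into k contiguous intervals (the first
  ``n_vars mod k`` intervals one point longer) and exhaustively scores every
  union of m intervals; deterministic.
* CARS (competitive adaptive reweighted sampling) runs a Monte-Carlo loop:
  each run fits PLS on a row subsample, enforces an exponentially decaying
  retention schedule on |coefficient| (keeping all p variables on the first
  run and exactly 2 on the last), then resamples variables with
  |coefficient|-proportional weights; the run whose retained set scores the
  lowest RMSECV wins.
* Random frog is a reversible-jump-style walk over variable subsets whose
  per-variable visit frequencies become selection probabilities; the final
  subset is the best top-j probability cut over a grid of j.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pls import coefficient_paths, cv_rmsecv

__all__ = [
    "VariableSubset",
    "interval_bounds",
    "sipls_select",
    "cars_schedule",
    "retained_counts",
    "cars_select",
    "random_frog_select",
]


@dataclass(frozen=True)
class VariableSubset:
    """A selected set of wavenumber positions with provenance."""

    indices: tuple[int, ...]
    method: str  # sipls | cars | random_frog
    rmsecv: float
    n_lvs: int
    hyperparams: dict = field(default_factory=dict)
    selection_probabilities: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        if idx != tuple(int(i) for i in self.indices):
            object.__setattr__(self, "indices", idx)
        if any(i < 0 for i in self.indices):
            raise ValueError("negative variable index")
        if not math.isfinite(self.rmsecv) or self.rmsecv < 0:
            raise ValueError("rmsecv must be finite and >= 0")
        if self.selection_probabilities is not None:
            probs = np.asarray(self.selection_probabilities, dtype=float)
            if probs.min() < 0 or probs.max() > 1:
                raise ValueError("selection probabilities must lie in [0, 1]")
            object.__setattr__(self, "selection_probabilities", probs)

    @property
    def n_selected(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# SIPLS
# ---------------------------------------------------------------------------

def interval_bounds(n_vars: int, k: int) -> list[tuple[int, int]]:
    """k contiguous [start, stop) intervals; first n_vars % k are one longer."""
    if not 1 <= k <= n_vars:
        raise ValueError(f"k must be in [1, {n_vars}]")
    base, extra = divmod(n_vars, k)
    bounds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def sipls_select(
    X: np.ndarray,
    y: np.ndarray,
    k_intervals: int,
    m_combine: int,
    max_lvs: int = 10,
    cv: int = 5,
    max_combinations: int = 20_000,
) -> VariableSubset:
    """Exhaustive synergy-interval search: best union of m of k intervals.

    Ties in RMSECV break toward the lexicographically smallest interval
    tuple (enumeration order), so the result is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= m_combine <= k_intervals <= p:
        raise ValueError("need 1 <= m_combine <= k_intervals <= n_vars")
    n_comb = math.comb(k_intervals, m_combine)
    if n_comb > max_combinations:
        raise ValueError(
            f"C({k_intervals},{m_combine}) = {n_comb} exceeds the combinatorial budget "
            f"({max_combinations}); use smaller k or m"
        )
    bounds = interval_bounds(p, k_intervals)
    best: tuple[float, tuple[int, ...], int] | None = None
    for combo in itertools.combinations(range(k_intervals), m_combine):
        idx = np.concatenate([np.arange(*bounds[i]) for i in combo])
        rmsecv, lvs = cv_rmsecv(X[:, idx], y, max_lvs=max_lvs, cv=cv)
        if best is None or rmsecv < best[0]:
            best = (rmsecv, combo, lvs)
    rmsecv, combo, lvs = best  # type: ignore[misc]
    idx = np.concatenate([np.arange(*bounds[i]) for i in combo])
    return VariableSubset(
        indices=tuple(int(i) for i in idx),
        method="sipls",
        rmsecv=rmsecv,
        n_lvs=lvs,
        hyperparams={"k_intervals": k_intervals, "m_combine": m_combine,
                     "intervals": tuple(combo), "cv": cv, "max_lvs": max_lvs},
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decaying retention fractions r_i = a * exp(-k*i).

    Calibrated so that ceil(r_1 * p) == p and ceil(r_N * p) == 2: with
    a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1), r_1 = 1 and r_N = 2/p.
    """
    if n_runs < 2:
        raise ValueError("CARS needs at least 2 runs")
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    # a * exp(-k*i) algebraically equals (p/2) ** ((1 - i)/(n_runs - 1))
    i = np.arange(1, n_runs + 1)
    return (p / 2.0) ** ((1.0 - i) / (n_runs - 1))


def retained_counts(p: int, n_runs: int) -> np.ndarray:
    """Integer retention schedule ceil(r_i * p), guarded against float dust:
    starts at exactly p and ends at exactly 2."""
    return np.ceil(cars_schedule(p, n_runs) * p - 1e-9).astype(int)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    mc_ratio: float = 0.8,
    cv: int = 5,
    max_lvs: int = 10,
    seed: int = 0,
) -> VariableSubset:
    """Competitive adaptive reweighted sampling over ``n_runs`` Monte-Carlo runs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 0 < mc_ratio < 1:
        raise ValueError("mc_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    keep_schedule = retained_counts(p, n_runs)
    n_sub = max(2, int(math.floor(mc_ratio * n)))

    current = np.arange(p)
    best: tuple[float, np.ndarray, int] | None = None
    for i, n_keep in enumerate(keep_schedule):
        rows = rng.choice(n, size=n_sub, replace=False)
        lv_cap = min(max_lvs, n_sub - 1, current.size)
        B, _, _ = coefficient_paths(X[np.ix_(rows, current)], y[rows], lv_cap)
        coef = np.abs(B[:, -1])
        if n_keep < current.size:  # enforced elimination by |coefficient|
            order = np.argsort(-coef, kind="stable")[:n_keep]
            asc = np.argsort(current[order])
            current = current[order][asc]
            coef = coef[order][asc]
        total = coef.sum()
        if total > 0 and current.size > 2:  # adaptive reweighted sampling
            picks = rng.choice(current.size, size=n_keep, replace=True, p=coef / total)
            current = current[np.unique(picks)]
        if current.size < 2:
            warnings.warn(f"CARS retained set collapsed at run {i + 1}; schedule truncated")
            break
        rmsecv, lvs = cv_rmsecv(X[:, current], y, max_lvs=min(max_lvs, current.size), cv=cv)
        if best is None or rmsecv < best[0]:
            best = (rmsecv, current.copy(), lvs)
    if best is None:
        raise RuntimeError("CARS produced no valid subset")
    rmsecv, idx, lvs = best
    return VariableSubset(
        indices=tuple(int(i) for i in idx),
        method="cars",
        rmsecv=rmsecv,
        n_lvs=lvs,
        hyperparams={"n_runs": n_runs, "mc_ratio": mc_ratio, "cv": cv,
                     "max_lvs": max_lvs, "seed": seed},
    )


# ---------------------------------------------------------------------------
# random frog
# ---------------------------------------------------------------------------

def _abs_coef(X: np.ndarray, y: np.ndarray, cols: np.ndarray, max_lvs: int) -> np.ndarray:
    lv = min(max_lvs, X.shape[0] - 1, cols.size)
    B, _, _ = coefficient_paths(X[:, cols], y, lv)
    return np.abs(B[:, -1])


def random_frog_select(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 1000,
    q0: int | None = None,
    theta: float = 0.3,
    omega: float = 3.0,
    eta: float = 0.1,
    top_grid: Sequence[int] | None = None,
    cv: int = 5,
    max_lvs: int = 10,
    seed: int = 0,
) -> VariableSubset:
    """Random-frog stochastic subset walk with per-variable selection probabilities.

    Each iteration proposes a new subset dimension Q* ~ round(N(Q, theta*Q));
    shrinking keeps the strongest |coefficient| members, growing auctions
    omega*(Q*-Q) randomly drawn outsiders by their coefficients in a joint
    model.  Proposals are accepted on RMSECV (with a small Metropolis-like
    escape probability eta).  Probabilities = visit tally / n_iter; the final
    subset is the best top-j cut over ``top_grid``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if q0 is None:
        q0 = max(2, int(round(0.1 * p)))
    if not 1 <= q0 <= p:
        raise ValueError(f"q0 must be in [1, {p}]")
    rng = np.random.default_rng(seed)

    current = np.sort(rng.choice(p, size=q0, replace=False))
    current_rmsecv, _ = cv_rmsecv(X[:, current], y, max_lvs=min(max_lvs, current.size), cv=cv)
    tally = np.zeros(p)
    for _ in range(n_iter):
        q = current.size
        q_star = int(np.clip(round(rng.normal(q, theta * q)), 1, p))
        if q_star < q:
            coef = _abs_coef(X, y, current, max_lvs)
            keep = np.argsort(-coef, kind="stable")[:q_star]
            candidate = np.sort(current[keep])
        elif q_star > q:
            outside = np.setdiff1d(np.arange(p), current, assume_unique=False)
            n_draw = min(outside.size, max(q_star - q, int(round(omega * (q_star - q)))))
            if n_draw == 0:
                candidate = current
            else:
                drawn = rng.choice(outside, size=n_draw, replace=False)
                union = np.sort(np.concatenate([current, drawn]))
                coef = _abs_coef(X, y, union, max_lvs)
                drawn_pos = np.searchsorted(union, np.sort(drawn))
                order = np.argsort(-coef[drawn_pos], kind="stable")
                add = np.sort(drawn)[order[: q_star - q]]
                candidate = np.sort(np.concatenate([current, add]))
        else:
            candidate = current
        if candidate is current:
            cand_rmsecv = current_rmsecv
        else:
            cand_rmsecv, _ = cv_rmsecv(X[:, candidate], y, max_lvs=min(max_lvs, candidate.size), cv=cv)
        if cand_rmsecv <= current_rmsecv or rng.random() < eta * (current_rmsecv / cand_rmsecv):
            current, current_rmsecv = candidate, cand_rmsecv
        tally[current] += 1

    probs = tally / n_iter
    if top_grid is None:
        fracs = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
        top_grid = sorted({max(2, int(round(f * p))) for f in fracs})
    order = np.argsort(-probs, kind="stable")
    best: tuple[float, int, int] | None = None
    for j in top_grid:
        j = min(int(j), p)
        idx = np.sort(order[:j])
        rmsecv, lvs = cv_rmsecv(X[:, idx], y, max_lvs=min(max_lvs, j), cv=cv)
        if best is None or rmsecv < best[0]:
            best = (rmsecv, j, lvs)
    rmsecv, j, lvs = best  # type: ignore[misc]
    return VariableSubset(
        indices=tuple(int(i) for i in np.sort(order[:j])),
        method="random_frog",
        rmsecv=rmsecv,
        n_lvs=lvs,
        hyperparams={"n_iter": n_iter, "q0": q0, "theta": theta, "omega": omega,
                     "eta": eta, "cv": cv, "max_lvs": max_lvs, "seed": seed,
                     "top_j": j},
        selection_probabilities=probs,
    )
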