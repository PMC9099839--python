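"""Sample-set partitioning: random external-validation holdout and SPXY.

SPXY (sample set partitioning based on joint x-y distance) picks a
calibration set that spans both the spectral space and the reference-value
range.  Pairwise distances are Euclidean on the spectra (dx) and absolute
difference on the single reference indicator (dy); each is normalized by
its maximum, and the joint distance is their sum.  Selection is
Kennard-Stone-style max-min: seed with the pair at maximum joint distance,
then repeatedly add the sample whose minimum distance to the selected set
is largest.  Ties break toward the lowest row index, so the split is
deterministic.

Because dy uses the indicator being modelled, each indicator gets its own
calibration/prediction division.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_core import Split

__all__ = ["random_holdout", "spxy_split", "spxy_select_indices"]


def random_holdout(ids: Sequence[str], fraction: float, seed: int) -> tuple[str, ...]:
    """Sample ceil(fraction*n) ids without replacement (external validation)."""
    if not 0 <= fraction < 1:
        raise ValueError("holdout fraction must be in [0, 1)")
    ids = tuple(ids)
    n_val = int(np.ceil(fraction * len(ids)))
    if n_val == 0:
        return ()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_val, replace=False)
    return tuple(ids[i] for i in sorted(chosen))


def spxy_select_indices(X: np.ndarray, y: np.ndarray, n_cal: int) -> np.ndarray:
    """Row indices of the SPXY calibration set (sorted ascending)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("X and y have different numbers of samples")
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [2, {n}]")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0 and dy_max == 0:
        raise ValueError("all samples identical in both x and y; SPXY distance is degenerate")
    d = (dx / dx_max if dx_max > 0 else dx) + (dy / dy_max if dy_max > 0 else dy)

    # seed: pair with maximal joint distance, ties toward lowest (i, j)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_d = d[:, selected].min(axis=1)
    while len(selected) < n_cal:
        cand = remaining[int(np.argmax(min_d[remaining]))]  # argmax keeps first (lowest index) on ties
        selected.append(cand)
        remaining.remove(cand)
        min_d = np.minimum(min_d, d[:, cand])
    return np.array(sorted(selected))


def spxy_split(
    X: np.ndarray,
    y: np.ndarray,
    ids: Sequence[str],
    n_cal: int | None = None,
    cal_fraction: float = 0.75,
    validation_ids: Sequence[str] = (),
) -> Split:
    """SPXY calibration/prediction split over the given (pretreated) rows.

    ``n_cal`` defaults to round(0.75 * n) — the 3:1 division that yields
    67/23 for 90 modelling samples.  ``validation_ids`` are carried through
    into the returned Split untouched; X/y/ids must exclude them.
    """
    ids = tuple(ids)
    if n_cal is None:
        # round half down: 0.75 * 90 = 67.5 -> 67 (the 67/23 division)
        n_cal = int(np.ceil(cal_fraction * len(ids) - 0.5))
    cal_idx = spxy_select_indices(X, y, n_cal)
    cal_set = set(cal_idx.tolist())
    return Split(
        calibration_ids=tuple(ids[i] for i in cal_idx),
        prediction_ids=tuple(ids[i] for i in range(len(ids)) if i not in cal_set),
        validation_ids=tuple(validation_ids),
    )
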