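"""Spectral pretreatments and the empty-vial difference spectrum.

Four row-wise pretreatments are compared during model search — vector
normalization, standard normal variate (SNV), Savitzky-Golay (SG)
smoothing, and multiplicative scatter correction (MSC) — plus the identity
("raw").  MSC is the only stateful one: its reference spectrum is the mean
of the *calibration* spectra and is frozen before prediction or external
validation samples are ever transformed, so no information leaks across the
split.

`subtract_vial` implements the non-invasive difference spectrum: the
through-vial sample spectrum minus its matched empty-vial spectrum, leaving
(approximately) the liquid's contribution at the longer path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .io_core import AcquisitionMode, SpectraSet

__all__ = ["PRETREATMENTS", "PretreatmentSpec", "fit_apply_pretreatment", "subtract_vial"]

PRETREATMENTS = ("raw", "normalization", "snv", "sg", "msc")


@dataclass(frozen=True)
class PretreatmentSpec:
    """A pretreatment method plus its parameters and (for MSC) fitted state.

    ``norm_kind`` switches the unspecific "normalization" between the
    unit-vector (L2) default and min-max row scaling.
    """

    method: str = "raw"
    window: int = 11  # SG window length, odd
    polyorder: int = 2  # SG polynomial order
    deriv: int = 0  # SG derivative order
    norm_kind: str = "l2"  # "l2" | "minmax"
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in PRETREATMENTS:
            raise ValueError(f"unknown pretreatment {self.method!r}; expected one of {PRETREATMENTS}")
        if self.method == "sg":
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError("SG window must be odd and greater than the polynomial order")
            if self.deriv < 0:
                raise ValueError("SG derivative order must be >= 0")
        if self.norm_kind not in ("l2", "minmax"):
            raise ValueError("norm_kind must be 'l2' or 'minmax'")
        if self.msc_reference is not None:
            object.__setattr__(self, "msc_reference", np.asarray(self.msc_reference, dtype=float))

    @property
    def is_fitted(self) -> bool:
        return self.method != "msc" or self.msc_reference is not None


def _rowwise_normalize(A: np.ndarray, ids, kind: str) -> np.ndarray:
    if kind == "l2":
        norms = np.linalg.norm(A, axis=1)
        bad = np.nonzero(norms == 0)[0]
        if bad.size:
            raise ValueError(f"zero-norm spectrum for sample {ids[bad[0]]!r}")
        return A / norms[:, None]
    span = A.max(axis=1) - A.min(axis=1)
    bad = np.nonzero(span == 0)[0]
    if bad.size:
        raise ValueError(f"constant spectrum for sample {ids[bad[0]]!r}")
    return (A - A.min(axis=1)[:, None]) / span[:, None]


def _snv(A: np.ndarray, ids) -> np.ndarray:
    sd = A.std(axis=1, ddof=1)
    bad = np.nonzero(np.ptp(A, axis=1) == 0)[0]  # exact constant rows
    if bad.size:
        raise ValueError(f"zero-variance spectrum for sample {ids[bad[0]]!r}")
    return (A - A.mean(axis=1)[:, None]) / sd[:, None]


def _msc(A: np.ndarray, ids, reference: np.ndarray) -> np.ndarray:
    # regress each row on the reference; corrected row = (row - intercept)/slope
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    slopes = (A - A.mean(axis=1)[:, None]) @ ref_c / denom
    bad = np.nonzero(slopes == 0)[0]
    if bad.size:
        raise ValueError(f"zero MSC slope for sample {ids[bad[0]]!r}")
    intercepts = A.mean(axis=1) - slopes * reference.mean()
    return (A - intercepts[:, None]) / slopes[:, None]


def fit_apply_pretreatment(
    spectra: SpectraSet,
    spec: PretreatmentSpec,
    fit: bool = True,
) -> tuple[SpectraSet, PretreatmentSpec]:
    """Apply a pretreatment; with ``fit`` learn any state from these spectra.

    Returns the transformed SpectraSet (same wavenumber grid) and the fitted
    spec.  For MSC with ``fit=False`` the spec must already carry its
    reference spectrum.
    """
    A = spectra.absorbance
    if A.size == 0:
        raise ValueError("empty spectra matrix")
    ids = spectra.sample_ids
    if spec.method == "raw":
        out = A.copy()
    elif spec.method == "normalization":
        out = _rowwise_normalize(A, ids, spec.norm_kind)
    elif spec.method == "snv":
        out = _snv(A, ids)
    elif spec.method == "sg":
        out = savgol_filter(
            A, window_length=spec.window, polyorder=spec.polyorder,
            deriv=spec.deriv, axis=1, mode="interp",
        )
    elif spec.method == "msc":
        if fit:
            spec = replace(spec, msc_reference=A.mean(axis=0))
        if spec.msc_reference is None:
            raise ValueError("MSC applied to new samples before fitting a reference spectrum")
        if spec.msc_reference.size != A.shape[1]:
            raise ValueError("MSC reference length does not match spectra grid")
        out = _msc(A, ids, spec.msc_reference)
    else:  # pragma: no cover - guarded by PretreatmentSpec
        raise AssertionError(spec.method)
    return spectra.with_absorbance(out), spec


def subtract_vial(sample: SpectraSet, vial: SpectraSet) -> SpectraSet:
    """Through-vial spectrum minus the matched empty-vial spectrum.

    Sample ids must match 1:1 in order and the grids must be identical; the
    result is tagged with the ``difference`` mode.
    """
    if sample.sample_ids != vial.sample_ids:
        raise ValueError("sample/vial id mismatch: difference spectra need 1:1 matched vials")
    if sample.wavenumbers.shape != vial.wavenumbers.shape or not np.allclose(
        sample.wavenumbers, vial.wavenumbers, rtol=0, atol=1e-9
    ):
        raise ValueError("sample and vial spectra are on different wavenumber grids")
    return sample.with_absorbance(
        sample.absorbance - vial.absorbance, mode=AcquisitionMode.DIFFERENCE
    )
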