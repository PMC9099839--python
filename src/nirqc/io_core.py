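"""Domain containers and delimited-text I/O for the NIR quality-control pipeline.

The pipeline's x-block is a :class:`SpectraSet` — a samples x wavenumbers
absorbance matrix tagged with the acquisition mode (traditional 4 mm scanning
tube, through-vial ~12 mm, empty vial, or a sample-minus-vial difference).
The y-block is a :class:`ReferenceTable` holding the anti-inflammatory
endpoint (ANTI-NO, the fractional inhibition of nitric-oxide production in
LPS-stimulated RAW 264.7 macrophages) and the three marker concentrations of
Lanqin oral solution: epigoitrin, geniposide and baicalin, all in mg/mL.

Conventions fixed here and relied on everywhere else:

* wavenumbers are stored strictly descending (instrument order,
  10,000 -> 4000 cm^-1) on a uniform grid; variable indices are 0-based
  positions in this descending grid;
* ANTI-NO is stored as a fraction internally; reports may expose percent;
* all delimited text is comma-separated, '.' decimal, UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMode",
    "SpectraSet",
    "ReferenceTable",
    "Split",
    "INDICATORS",
    "DEFAULT_WAVENUMBERS",
    "default_grid",
    "load_spectra",
    "write_spectra",
    "load_references",
    "write_references",
    "join_by_sample_id",
]

#: indicator column names of the reference table, in report order
INDICATORS = ("anti_no", "epigoitrin", "geniposide", "baicalin")

_GRID_RTOL = 1e-6


class AcquisitionMode(str, Enum):
    """How a spectrum was acquired."""

    TRADITIONAL = "traditional"  # 4 mm quartz scanning tube
    THROUGH_VIAL = "through_vial"  # intact commercial vial, ~12 mm path
    EMPTY_VIAL = "empty_vial"  # vial without liquid
    DIFFERENCE = "difference"  # through-vial minus matched empty vial


def default_grid(n_points: int = 1557, high: float = 10_000.0, low: float = 4_000.0) -> np.ndarray:
    """Uniform descending wavenumber grid, 10,000 -> 4000 cm^-1, 1557 points."""
    return np.linspace(high, low, n_points)


DEFAULT_WAVENUMBERS = default_grid()


def _check_uniform_descending(wavenumbers: np.ndarray) -> None:
    if wavenumbers.ndim != 1 or wavenumbers.size < 2:
        raise ValueError("wavenumber grid must be 1-D with at least 2 points")
    gaps = np.diff(wavenumbers)
    if not np.all(gaps < 0):
        raise ValueError("wavenumbers must be strictly monotonic descending")
    mean_gap = gaps.mean()
    bad = np.nonzero(np.abs(gaps - mean_gap) > abs(mean_gap) * _GRID_RTOL)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform wavenumber spacing: gap {gaps[i]:.6g} cm^-1 between "
            f"{wavenumbers[i]:.6g} and {wavenumbers[i + 1]:.6g} (expected {mean_gap:.6g})"
        )


def _check_unique_ids(sample_ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"duplicate sample id: {sid!r}")
        seen.add(sid)


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance matrix (n_samples x n_vars) on a shared wavenumber grid."""

    sample_ids: tuple[str, ...]
    wavenumbers: np.ndarray  # cm^-1, strictly descending, uniform
    absorbance: np.ndarray  # AU, shape (n_samples, n_vars)
    mode: AcquisitionMode = AcquisitionMode.TRADITIONAL
    path_length_mm: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        _check_unique_ids(self.sample_ids)
        _check_uniform_descending(wn)
        if ab.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if ab.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {ab.shape[0]} spectra rows"
            )
        if ab.shape[1] != wn.size:
            raise ValueError(f"{wn.size} wavenumbers but {ab.shape[1]} absorbance columns")
        if not np.all(np.isfinite(ab)):
            r, c = np.argwhere(~np.isfinite(ab))[0]
            raise ValueError(
                f"non-finite absorbance at sample {self.sample_ids[r]!r}, "
                f"wavenumber {wn[c]:.6g} cm^-1"
            )
        if not self.path_length_mm > 0:
            raise ValueError("path_length_mm must be positive")
        object.__setattr__(self, "mode", AcquisitionMode(self.mode))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_vars(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, mode: AcquisitionMode | None = None) -> "SpectraSet":
        """Same grid/ids, new matrix (and optionally a new mode tag)."""
        return replace(self, absorbance=absorbance, mode=self.mode if mode is None else mode)

    def subset_samples(self, ids: Sequence[str]) -> "SpectraSet":
        idx = [self._index_of(s) for s in ids]
        return replace(
            self,
            sample_ids=tuple(ids),
            absorbance=self.absorbance[idx, :],
        )

    def subset_variables(self, indices: Sequence[int]) -> np.ndarray:
        """Absorbance restricted to variable positions (view into a copy)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_vars):
            raise IndexError("variable index out of grid range")
        return self.absorbance[:, idx]

    def _index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample id {sample_id!r} not in SpectraSet") from None


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample reference values: ANTI-NO fraction + three analytes (mg/mL)."""

    sample_ids: tuple[str, ...]
    values: pd.DataFrame = field(repr=False)  # columns == INDICATORS, index == sample_ids

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique_ids(self.sample_ids)
        df = self.values.copy()
        missing = [c for c in INDICATORS if c not in df.columns]
        if missing:
            raise ValueError(f"reference table missing indicator column(s): {missing}")
        df = df.loc[:, list(INDICATORS)].astype(float)
        df.index = pd.Index(self.sample_ids, name="sample_id")
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            raise ValueError(f"missing values in modelled column {col!r}")
        for col in ("epigoitrin", "geniposide", "baicalin"):
            if (df[col] < 0).any():
                sid = df.index[df[col] < 0][0]
                raise ValueError(f"negative {col} concentration for sample {sid!r}")
        object.__setattr__(self, "values", df)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def indicator(self, name: str) -> np.ndarray:
        if name not in INDICATORS:
            raise KeyError(f"unknown indicator {name!r}; expected one of {INDICATORS}")
        return self.values[name].to_numpy()

    def subset_samples(self, ids: Sequence[str]) -> "ReferenceTable":
        df = self.values.loc[list(ids)]
        return ReferenceTable(sample_ids=tuple(ids), values=df)


@dataclass(frozen=True)
class Split:
    """Disjoint calibration / prediction / external-validation id sets."""

    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    validation_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = (self.calibration_ids, self.prediction_ids, self.validation_ids)
        all_ids = [sid for g in groups for sid in g]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split id sets are not pairwise disjoint")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.calibration_ids + self.prediction_ids + self.validation_ids

    def to_frame(self) -> pd.DataFrame:
        rows = [(sid, role) for role, ids in (
            ("calibration", self.calibration_ids),
            ("prediction", self.prediction_ids),
            ("validation", self.validation_ids),
        ) for sid in ids]
        return pd.DataFrame(rows, columns=["sample_id", "role"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_spectra(
    path: str | Path,
    mode: AcquisitionMode | str = AcquisitionMode.TRADITIONAL,
    path_length_mm: float | None = None,
) -> SpectraSet:
    """Read a spectra CSV: first column sample id, remaining headers wavenumbers.

    Columns are reordered to the descending-wavenumber convention regardless
    of file order; the data move with them.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    try:
        wn = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric wavenumber header in {path}: {exc}") from exc
    mat = df.to_numpy()
    if not np.issubdtype(mat.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna()][0]
                raise ValueError(f"non-numeric absorbance at row {row!r}, column {col!r}")
        mat = df.apply(pd.to_numeric).to_numpy()
    order = np.argsort(-wn, kind="stable")
    mode = AcquisitionMode(mode)
    if path_length_mm is None:
        path_length_mm = 12.0 if mode in (AcquisitionMode.THROUGH_VIAL, AcquisitionMode.EMPTY_VIAL) else 4.0
    return SpectraSet(
        sample_ids=tuple(str(s) for s in df.index),
        wavenumbers=wn[order],
        absorbance=mat[:, order],
        mode=mode,
        path_length_mm=path_length_mm,
    )


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[format(float(w), ".17g") for w in spectra.wavenumbers],
    )
    df.to_csv(path, float_format="%.17g")


def load_references(path: str | Path, anti_no_is_percent: bool = False) -> ReferenceTable:
    """Read the reference CSV (id column + the four indicator columns).

    ANTI-NO is stored as a fraction. Values > 1.5 are rejected as probable
    percent/fraction confusion unless ``anti_no_is_percent`` is set, in which
    case the column is divided by 100 on load.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    missing = [c for c in INDICATORS if c not in df.columns]
    if missing:
        raise ValueError(f"reference file {path} missing column(s): {missing}")
    if anti_no_is_percent:
        df["anti_no"] = df["anti_no"] / 100.0
    elif (df["anti_no"] > 1.5).any():
        sid = df.index[df["anti_no"] > 1.5][0]
        raise ValueError(
            f"anti_no={df.loc[sid, 'anti_no']} for sample {sid!r} looks like a percent; "
            "pass anti_no_is_percent=True if the file stores percentages"
        )
    return ReferenceTable(sample_ids=tuple(str(s) for s in df.index), values=df)


def write_references(refs: ReferenceTable, path: str | Path) -> None:
    refs.values.to_csv(path, float_format="%.17g")


def join_by_sample_id(
    spectra: SpectraSet,
    refs: ReferenceTable,
    allow_partial: bool = False,
) -> tuple[SpectraSet, ReferenceTable]:
    """Align x and y blocks on sample id; row order follows the spectra.

    In strict mode (default) any id present on one side only is an error;
    with ``allow_partial`` those samples are dropped and reported via the
    return value's reduced id set.
    """
    spec_ids = set(spectra.sample_ids)
    ref_ids = set(refs.sample_ids)
    common = [sid for sid in spectra.sample_ids if sid in ref_ids]
    if not common:
        raise ValueError("no sample ids common to spectra and reference table")
    missing = sorted((spec_ids - ref_ids) | (ref_ids - spec_ids))
    if missing and not allow_partial:
        raise ValueError(f"sample ids missing from one side: {missing}")
    return spectra.subset_samples(common), refs.subset_samples(common)


def write_manifest(path: str | Path, **entries: object) -> None:
    """JSON run manifest (config, seeds, versions)."""
    payload = dict(entries)
    payload.setdefault("versions", {})
    import nirqc

    payload["versions"] = {
        "nirqc": nirqc.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **payload["versions"],  # type: ignore[dict-item]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
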