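"""Synthetic paired NIR spectra and reference values for Lanqin oral solution.

The study conditions emulated here: 101 commercial batches (35 measured as
sold, 66 diluted with water to widen the concentration range), scanned three
ways — a traditional 4 mm scanning tube, through the intact ~12 mm brown
glass vial, and the matching empty vial — with per-sample reference values
for epigoitrin, geniposide, baicalin (HPLC, mg/mL) and the ANTI-NO
bioactivity endpoint (fractional inhibition of nitric-oxide production in
LPS-stimulated RAW 264.7 macrophages, Griess assay).

Spectra follow a Beer-Lambert mixture model: each chemical component (plus
water and a latent "matrix" component standing in for the several hundred
unresolved constituents of the five-herb decoction) contributes a sum of
Gaussian bands; the traditional spectrum is the 4 mm mixture plus a low-order
polynomial baseline, per-sample multiplicative scatter, and white noise.  The
through-vial spectrum scales the mixture by the path ratio (12/4 = 3) and adds
a smooth, slightly vial-specific glass spectrum; the empty-vial spectrum is
that glass spectrum alone plus noise.  Band positions follow the liquid's NIR
assignments: the water O-H first overtone near 6900 cm^-1, the O-H combination
band near 5150 cm^-1, and C-H overtone structure over 8800-8000 cm^-1.

Bioactivity is simulated through the assay itself: per-batch NO
concentrations for the model group (Cm) and control group (Cc) are drawn,
the drug group responds as Cd = Cm - (Cm - Cc) * f with
f = logistic(w . c + latent + intercept), and ANTI-NO is computed from the
three concentrations exactly as the assay computes it.  The logistic keeps
activity in a narrow band for undiluted batches while concentrations vary
~3-fold, and ties it to all components at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AcquisitionMode,
    ReferenceTable,
    SpectraSet,
    default_grid,
)

__all__ = [
    "ComponentProfile",
    "SyntheticConfig",
    "SyntheticBundle",
    "anti_no_inhibition",
    "generate_pure_components",
    "generate_dataset",
    "planted_design",
    "DEFAULT_BANDS",
    "DEFAULT_CONCENTRATION_RANGES",
]

ANALYTES = ("epigoitrin", "geniposide", "baicalin")

#: mg/mL ranges of the undiluted commercial batches
DEFAULT_CONCENTRATION_RANGES: Mapping[str, tuple[float, float]] = {
    "epigoitrin": (0.02546, 0.0702),
    "geniposide": (2.388, 7.413),
    "baicalin": (0.9230, 3.131),
}

#: Gaussian bands (center cm^-1, width cm^-1, amplitude AU.mL/mg at the 4 mm path)
DEFAULT_BANDS: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    # water dominates the liquid spectrum; "concentration" is its volume fraction (~1)
    "water": ((6900.0, 280.0, 0.55), (5150.0, 210.0, 0.75), (8700.0, 350.0, 0.08), (4350.0, 150.0, 0.25)),
    # S/N-bearing high-wavenumber structure plus the C=C region near 6050
    "epigoitrin": ((9100.0, 120.0, 1.2), (8600.0, 150.0, 1.0), (8200.0, 100.0, 0.8),
                   (6050.0, 90.0, 0.9), (4600.0, 80.0, 0.7), (4200.0, 70.0, 0.6)),
    # iridoid C-H overtones: 8242-7351 second overtone plus the 6100 C=C C-H band
    "geniposide": ((8100.0, 200.0, 0.010), (7600.0, 150.0, 0.008), (6100.0, 100.0, 0.012),
                   (5900.0, 120.0, 0.006), (4750.0, 90.0, 0.008), (4300.0, 80.0, 0.006)),
    # benzene-ring C-H/C-C below 5400 with the sharp 4065 band and phenolic O-H near 7000
    "baicalin": ((5280.0, 100.0, 0.030), (4800.0, 120.0, 0.025), (4400.0, 90.0, 0.035),
                 (4065.0, 60.0, 0.040), (7000.0, 150.0, 0.020), (5600.0, 80.0, 0.020)),
    # everything else in the decoction, lumped
    "matrix": ((8900.0, 300.0, 0.020), (7200.0, 250.0, 0.030), (6500.0, 200.0, 0.025),
               (5700.0, 220.0, 0.030), (4900.0, 180.0, 0.025), (4200.0, 150.0, 0.020)),
}

#: logistic weights tying activity to every component (per mg/mL; matrix per unit)
DEFAULT_ACTIVITY_WEIGHTS: Mapping[str, float] = {
    "epigoitrin": 10.0,
    "geniposide": 0.18,
    "baicalin": 0.36,
    "matrix": 0.7,
}
DEFAULT_ACTIVITY_INTERCEPT = -1.2


def anti_no_inhibition(c_model: float, c_drug: float, c_control: float):
    """ANTI-NO inhibition fraction from Griess-assay NO concentrations.

    ANTI-NO = (Cm - Cd) / (Cm - Cc), with Cm/Cd/Cc the NO concentrations of
    the model, drug and control groups.  The value may leave [0, 1] when the
    drug group falls below the control; it is reported, not clipped.
    """
    c_model = np.asarray(c_model, dtype=float)
    c_drug = np.asarray(c_drug, dtype=float)
    c_control = np.asarray(c_control, dtype=float)
    denom = c_model - c_control
    if np.any(denom == 0):
        raise ZeroDivisionError("Cm == Cc: ANTI-NO denominator is undefined")
    out = (c_model - c_drug) / denom
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ComponentProfile:
    """A pure-component NIR profile as a sum of Gaussian bands."""

    name: str
    bands: tuple[tuple[float, float, float], ...]  # (center, width, amplitude)

    def __post_init__(self) -> None:
        for center, width, amp in self.bands:
            if width <= 0:
                raise ValueError(f"{self.name}: band width must be positive (center {center})")
            if amp < 0:
                raise ValueError(f"{self.name}: band amplitude must be non-negative (center {center})")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Profile on the grid; every band center must lie within the grid."""
        wn = np.asarray(wavenumbers, dtype=float)
        lo, hi = wn.min(), wn.max()
        out = np.zeros_like(wn)
        for center, width, amp in self.bands:
            if not lo <= center <= hi:
                raise ValueError(
                    f"{self.name}: band center {center} cm^-1 outside grid [{lo}, {hi}]"
                )
            out += amp * np.exp(-0.5 * ((wn - center) / width) ** 2)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator conditions; defaults emulate the 101-batch study."""

    n_undiluted: int = 35
    n_diluted: int = 66
    dilution_factors: tuple[float, ...] = (1.25, 1.67, 2.5, 5.0)
    concentration_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATION_RANGES)
    )
    bands: Mapping[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    n_points: int = 1557
    wavenumber_high: float = 10_000.0
    wavenumber_low: float = 4_000.0
    baseline_degree: int = 2
    baseline_amplitude: float = 0.03  # AU, uniform coefficient bound
    scatter_sd: float = 0.02  # relative multiplicative spread
    noise_sd: float = 0.002  # AU
    vial_amplitude: float = 0.1  # AU scale of the glass spectrum
    vial_batch_sd: float = 0.1  # relative vial-to-vial coefficient spread
    path_ratio: float = 3.0  # through-vial / traditional path (12 mm / 4 mm)
    matrix_mean: float = 1.0
    matrix_sd: float = 0.15
    water_sd: float = 0.003
    activity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_WEIGHTS)
    )
    activity_intercept: float = DEFAULT_ACTIVITY_INTERCEPT
    activity_latent_sd: float = 0.08  # logit-scale latent biology
    assay_cm_mean: float = 45.0  # µM NO, model group
    assay_cm_sd: float = 2.0
    assay_cc_mean: float = 8.0  # µM NO, control group
    assay_cc_sd: float = 1.0
    assay_noise_sd: float = 0.5  # µM on the drug-group NO concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_undiluted < 0 or self.n_diluted < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_diluted > 0 and self.n_undiluted == 0:
            raise ValueError("diluted samples need undiluted parents")
        if any(f < 1 for f in self.dilution_factors):
            raise ValueError("dilution factors must be >= 1")
        for name, (lo, hi) in self.concentration_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid concentration range for {name}")
        for sd in (self.scatter_sd, self.noise_sd, self.vial_batch_sd,
                   self.activity_latent_sd, self.assay_noise_sd, self.matrix_sd, self.water_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.path_ratio <= 0:
            raise ValueError("path_ratio must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_undiluted + self.n_diluted

    def grid(self) -> np.ndarray:
        return default_grid(self.n_points, self.wavenumber_high, self.wavenumber_low)


@dataclass(frozen=True)
class SyntheticBundle:
    """Paired traditional / through-vial / empty-vial spectra with references."""

    spectra_traditional: SpectraSet
    spectra_through_vial: SpectraSet
    spectra_empty_vial: SpectraSet
    references: ReferenceTable
    truth: pd.DataFrame  # true concentrations, dilution provenance, noiseless activity

    def __post_init__(self) -> None:
        ids = self.spectra_traditional.sample_ids
        for other in (self.spectra_through_vial, self.spectra_empty_vial):
            if other.sample_ids != ids:
                raise ValueError("bundle spectra sets do not share the sample-id set")
        if self.references.sample_ids != ids:
            raise ValueError("references do not share the bundle sample-id set")
        if not np.all(np.isfinite(self.truth.select_dtypes("number").to_numpy())):
            raise ValueError("non-finite truth values")


def generate_pure_components(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Each component profile evaluated on the config's wavenumber grid."""
    grid = config.grid()
    return {
        name: ComponentProfile(name, tuple(tuple(b) for b in bands)).evaluate(grid)
        for name, bands in config.bands.items()
    }


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticBundle:
    """Draw one full 101-batch-style bundle; identical seed -> identical bundle."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid()
    profiles = generate_pure_components(config)
    n = config.n_samples
    ids = tuple(f"S{i + 1:03d}" for i in range(n))

    # --- true concentrations -------------------------------------------------
    conc = {
        name: rng.uniform(lo, hi, size=config.n_undiluted)
        for name, (lo, hi) in config.concentration_ranges.items()
    }
    matrix_und = np.clip(
        rng.normal(config.matrix_mean, config.matrix_sd, size=config.n_undiluted), 0.05, None
    )
    factors = np.ones(n)
    parent = np.arange(n)
    if config.n_diluted:
        parent_idx = rng.integers(0, config.n_undiluted, size=config.n_diluted)
        fac = np.array([
            config.dilution_factors[i % len(config.dilution_factors)]
            for i in range(config.n_diluted)
        ])
        factors[config.n_undiluted:] = fac
        parent[config.n_undiluted:] = parent_idx
    full_conc = {
        name: vals[parent % config.n_undiluted] / factors
        for name, vals in conc.items()
    }
    matrix_conc = matrix_und[parent % config.n_undiluted] / factors
    water_conc = np.clip(rng.normal(1.0, config.water_sd, size=n), 0.5, None)

    # --- spectra -------------------------------------------------------------
    mixture = water_conc[:, None] * profiles["water"][None, :]
    mixture = mixture + matrix_conc[:, None] * profiles["matrix"][None, :]
    for name in config.concentration_ranges:
        mixture = mixture + full_conc[name][:, None] * profiles[name][None, :]

    u = np.linspace(-1.0, 1.0, grid.size)[None, :]
    base_coef = rng.uniform(-config.baseline_amplitude, config.baseline_amplitude,
                            size=(n, config.baseline_degree + 1))
    baseline = sum(base_coef[:, [d]] * u**d for d in range(config.baseline_degree + 1))
    scatter = rng.normal(1.0, config.scatter_sd, size=n)[:, None] if config.scatter_sd else np.ones((n, 1))

    vial_base = np.array([0.8, 0.15, 0.05])  # smooth, featureless glass curve
    vial_coef = vial_base[None, :] * (
        1.0 + rng.normal(0.0, config.vial_batch_sd, size=(n, 3))
    )
    vial = config.vial_amplitude * sum(vial_coef[:, [d]] * u**d for d in range(3))

    def noise() -> np.ndarray:
        return rng.normal(0.0, config.noise_sd, size=(n, grid.size)) if config.noise_sd else 0.0

    a_trad = scatter * mixture + baseline + noise()
    a_through = scatter * (config.path_ratio * mixture) + baseline + vial + noise()
    a_empty = vial + noise()

    # --- bioactivity via the simulated Griess assay --------------------------
    w = config.activity_weights
    logit = np.full(n, config.activity_intercept)
    for name in config.concentration_ranges:
        logit = logit + w.get(name, 0.0) * full_conc[name]
    logit = logit + w.get("matrix", 0.0) * matrix_conc
    latent = rng.normal(0.0, config.activity_latent_sd, size=n) if config.activity_latent_sd else 0.0
    f_true = _logistic(logit + latent)
    cm = rng.normal(config.assay_cm_mean, config.assay_cm_sd, size=n)
    cc = rng.normal(config.assay_cc_mean, config.assay_cc_sd, size=n)
    cd = cm - (cm - cc) * f_true + (
        rng.normal(0.0, config.assay_noise_sd, size=n) if config.assay_noise_sd else 0.0
    )
    anti_no = anti_no_inhibition(cm, cd, cc)

    refs = ReferenceTable(
        sample_ids=ids,
        values=pd.DataFrame(
            {"anti_no": anti_no, **{k: full_conc[k] for k in ANALYTES}},
            index=list(ids),
        ),
    )
    truth = pd.DataFrame(
        {
            **{f"true_{k}": full_conc[k] for k in ANALYTES},
            "true_matrix": matrix_conc,
            "dilution_factor": factors,
            "parent_id": [ids[p] for p in parent],
            "activity_noiseless": f_true,
        },
        index=pd.Index(list(ids), name="sample_id"),
    )

    def spectra(mat: np.ndarray, mode: AcquisitionMode, path: float) -> SpectraSet:
        return SpectraSet(sample_ids=ids, wavenumbers=grid, absorbance=np.asarray(mat, dtype=float) + np.zeros((n, grid.size)), mode=mode, path_length_mm=path)

    return SyntheticBundle(
        spectra_traditional=spectra(a_trad, AcquisitionMode.TRADITIONAL, 4.0),
        spectra_through_vial=spectra(a_through, AcquisitionMode.THROUGH_VIAL, 4.0 * config.path_ratio),
        spectra_empty_vial=spectra(a_empty, AcquisitionMode.EMPTY_VIAL, 4.0 * config.path_ratio),
        references=refs,
        truth=truth,
    )


def planted_design(
    n: int = 100,
    p: int = 200,
    planted: Sequence[int] = (10, 50, 90, 130, 170),
    effect: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benchmark design for variable selectors: iid Gaussian X, a handful of
    informative variables with effect size ``effect/noise_sd`` (default 5x),
    pure noise elsewhere.  Returns (X, y, planted_indices)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    idx = np.asarray(sorted(planted), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= p):
        raise ValueError("planted index outside design")
    y = X[:, idx] @ np.full(idx.size, effect) + rng.normal(0.0, noise_sd, size=n)
    return X, y, idx
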