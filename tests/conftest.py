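"""Shared fixtures: scaled-down synthetic bundles and search grids.

Unit and pipeline tests run on a reduced problem (fewer samples, a coarser
wavenumber grid, a lighter search grid) so the suite stays fast; the
acceptance tests use the full default study conditions where a criterion
calls for them.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirqc.pipeline import SearchGrid
from nirqc.synthetic import DEFAULT_BANDS, SyntheticConfig, generate_dataset


def small_config(**overrides) -> SyntheticConfig:
    defaults = dict(n_undiluted=14, n_diluted=14, n_points=240)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def noiseless_config(**overrides) -> SyntheticConfig:
    """Every stochastic nuisance off: pure Beer-Lambert mixtures + exact assay."""
    defaults = dict(
        n_undiluted=14, n_diluted=14, n_points=240,
        noise_sd=0.0, baseline_amplitude=0.0, scatter_sd=0.0,
        vial_batch_sd=0.0, water_sd=0.0,
        activity_latent_sd=0.0, assay_noise_sd=0.0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_dataset(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_grid() -> SearchGrid:
    return SearchGrid(
        max_lvs=8, selection_max_lvs=6, sipls_k=(6,), sipls_m=(2,),
        cars_runs=25, frog_iter=60,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Full study-condition bundle (101 samples, 1557 variables)."""
    return generate_dataset(SyntheticConfig(), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
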