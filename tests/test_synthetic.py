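"""Generator correctness: assay arithmetic, Beer-Lambert structure, determinism."""

import numpy as np
import pytest

from nirqc.io_core import default_grid
from nirqc.synthetic import (
    DEFAULT_BANDS,
    DEFAULT_CONCENTRATION_RANGES,
    ComponentProfile,
    SyntheticConfig,
    anti_no_inhibition,
    generate_dataset,
    generate_pure_components,
    planted_design,
)

from conftest import noiseless_config, small_config


class TestAntiNoInhibition:
    @pytest.mark.parametrize(
        "cm, cd, cc, expected",
        [(50, 50, 10, 0.0), (50, 10, 10, 1.0), (10, 4, 2, 0.75)],
    )
    def test_assay_arithmetic(self, cm, cd, cc, expected):
        assert anti_no_inhibition(cm, cd, cc) == pytest.approx(expected)

    def test_exceeds_unity_when_drug_below_control(self):
        assert anti_no_inhibition(50, 5, 10) > 1.0  # reported, not clipped

    def test_model_equals_control_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            anti_no_inhibition(10, 5, 10)


class TestPureComponents:
    def test_water_peaks_at_configured_centers(self):
        grid = default_grid()
        water = ComponentProfile("water", DEFAULT_BANDS["water"]).evaluate(grid)
        for center in (6900.0, 5150.0):
            i = int(np.argmin(np.abs(grid - center)))
            window = water[i - 5 : i + 6]
            assert window.max() == water[i]

    def test_zero_bands_gives_zero_profile(self):
        grid = default_grid(100)
        np.testing.assert_array_equal(ComponentProfile("none", ()).evaluate(grid), 0.0)

    def test_amplitude_linearity(self):
        grid = default_grid(200)
        one = ComponentProfile("c", ((7000.0, 100.0, 0.5),)).evaluate(grid)
        two = ComponentProfile("c", ((7000.0, 100.0, 1.0),)).evaluate(grid)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_off_grid_center_rejected(self):
        grid = default_grid(100)
        with pytest.raises(ValueError, match="outside grid"):
            ComponentProfile("c", ((3000.0, 100.0, 0.5),)).evaluate(grid)


def _single_component_config(conc, **extra):
    """Only geniposide carries bands; every nuisance term disabled."""
    bands = {name: () for name in DEFAULT_BANDS}
    bands["geniposide"] = DEFAULT_BANDS["geniposide"]
    ranges = {"epigoitrin": (0.0, 0.0), "geniposide": conc, "baicalin": (0.0, 0.0)}
    return noiseless_config(
        n_undiluted=10, n_diluted=0, bands=bands, concentration_ranges=ranges,
        vial_amplitude=0.0, **extra,
    )


class TestGenerateDataset:
    def test_degenerate_config_equates_modes(self):
        cfg = noiseless_config(vial_amplitude=0.0, path_ratio=1.0)
        b = generate_dataset(cfg, seed=3)
        np.testing.assert_array_equal(
            b.spectra_through_vial.absorbance, b.spectra_traditional.absorbance
        )
        np.testing.assert_array_equal(b.spectra_empty_vial.absorbance, 0.0)

    def test_beer_lambert_concentration_linearity(self):
        c = 3.0
        b1 = generate_dataset(_single_component_config((c, c)), seed=5)
        b2 = generate_dataset(_single_component_config((2 * c, 2 * c)), seed=5)
        np.testing.assert_allclose(
            b2.spectra_traditional.absorbance,
            2 * b1.spectra_traditional.absorbance,
            rtol=1e-10, atol=1e-14,
        )

    def test_band_center_slope_matches_profile(self):
        """Regression of absorbance on concentration recovers path x amplitude."""
        cfg = _single_component_config((1.0, 8.0))
        b = generate_dataset(cfg, seed=9)
        grid = cfg.grid()
        profile = generate_pure_components(cfg)["geniposide"]
        conc = b.truth["true_geniposide"].to_numpy()
        for center in (8100.0, 6100.0):
            j = int(np.argmin(np.abs(grid - center)))
            a = b.spectra_traditional.absorbance[:, j]
            slope = np.polyfit(conc, a, 1)[0]
            assert slope == pytest.approx(profile[j], abs=1e-8)
            a_tv = b.spectra_through_vial.absorbance[:, j]
            slope_tv = np.polyfit(conc, a_tv, 1)[0]
            assert slope_tv == pytest.approx(cfg.path_ratio * profile[j], abs=1e-8)

    def test_seed_reproducibility_bit_identical(self):
        cfg = small_config()
        b1 = generate_dataset(cfg, seed=21)
        b2 = generate_dataset(cfg, seed=21)
        np.testing.assert_array_equal(
            b1.spectra_through_vial.absorbance, b2.spectra_through_vial.absorbance
        )
        np.testing.assert_array_equal(
            b1.references.values.to_numpy(), b2.references.values.to_numpy()
        )
        assert b1.truth.equals(b2.truth)

    def test_dilution_divides_parent_concentrations_exactly(self):
        cfg = small_config()
        b = generate_dataset(cfg, seed=2)
        truth = b.truth
        diluted = truth[truth["dilution_factor"] > 1]
        assert len(diluted) == cfg.n_diluted
        for col in ("true_epigoitrin", "true_geniposide", "true_baicalin", "true_matrix"):
            parents = truth.loc[diluted["parent_id"], col].to_numpy()
            np.testing.assert_array_equal(
                diluted[col].to_numpy(), parents / diluted["dilution_factor"].to_numpy()
            )

    def test_default_ranges_bracket_study_ranges(self):
        cfg = SyntheticConfig()
        assert dict(cfg.concentration_ranges) == dict(DEFAULT_CONCENTRATION_RANGES)
        b = generate_dataset(cfg, seed=1)
        und = b.references.values.iloc[: cfg.n_undiluted]
        for name, (lo, hi) in DEFAULT_CONCENTRATION_RANGES.items():
            assert und[name].min() >= lo and und[name].max() <= hi
        # undiluted bioactivity spans the reported stable band (75.55%-88.97%)
        assert und["anti_no"].min() < 0.7555
        assert und["anti_no"].max() > 0.8897

    def test_bundle_shares_sample_ids(self, small_bundle):
        ids = small_bundle.spectra_traditional.sample_ids
        assert small_bundle.spectra_through_vial.sample_ids == ids
        assert small_bundle.spectra_empty_vial.sample_ids == ids
        assert small_bundle.references.sample_ids == ids
        assert len(ids) == 28


class TestPlantedDesign:
    def test_shapes_and_determinism(self):
        X1, y1, idx = planted_design(n=40, p=60, planted=(5, 20, 40), seed=4)
        X2, y2, _ = planted_design(n=40, p=60, planted=(5, 20, 40), seed=4)
        assert X1.shape == (40, 60) and y1.shape == (40,)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)
        assert list(idx) == sorted(idx)

    def test_signal_lives_on_planted_variables(self):
        X, y, idx = planted_design(n=200, p=50, planted=(3, 20), effect=1.0,
                                   noise_sd=0.2, seed=0)
        corr = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(50)])
        assert set(np.argsort(-corr)[:2]) == set(idx)
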