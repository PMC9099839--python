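"""Pretreatment transforms: definitions, idempotence, leakage-free MSC, vial subtraction."""

import numpy as np
import pytest

from nirqc.io_core import AcquisitionMode, SpectraSet, default_grid
from nirqc.preprocessing import PretreatmentSpec, fit_apply_pretreatment, subtract_vial
from nirqc.synthetic import generate_dataset, generate_pure_components

from conftest import noiseless_config


def make_spectra(A, mode=AcquisitionMode.TRADITIONAL):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    return SpectraSet(
        sample_ids=tuple(f"S{i}" for i in range(A.shape[0])),
        wavenumbers=default_grid(A.shape[1]),
        absorbance=A,
        mode=mode,
    )


@pytest.fixture
def spectra(rng):
    base = np.sin(np.linspace(0, 4, 60))
    A = 0.2 + rng.uniform(0.5, 2.0, (8, 1))*base + rng.normal(0, 0.01, (8, 60))
    return make_spectra(A)


class TestRowwiseTransforms:
    def test_snv_rows_standardized(self, spectra):
        out, _ = fit_apply_pretreatment(spectra, PretreatmentSpec(method="snv"))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_l2_normalization_unit_rows(self, spectra):
        out, _ = fit_apply_pretreatment(spectra, PretreatmentSpec(method="normalization"))
        np.testing.assert_allclose(np.linalg.norm(out.absorbance, axis=1), 1, rtol=1e-12)

    def test_minmax_variant_spans_unit_interval(self, spectra):
        out, _ = fit_apply_pretreatment(
            spectra, PretreatmentSpec(method="normalization", norm_kind="minmax")
        )
        np.testing.assert_allclose(out.absorbance.min(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.max(axis=1), 1, rtol=1e-12)

    @pytest.mark.parametrize("method", ["snv", "normalization"])
    def test_idempotence(self, spectra, method):
        spec = PretreatmentSpec(method=method)
        once, _ = fit_apply_pretreatment(spectra, spec)
        twice, _ = fit_apply_pretreatment(once, spec)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, rtol=1e-10, atol=1e-12)

    def test_raw_is_identity(self, spectra):
        out, _ = fit_apply_pretreatment(spectra, PretreatmentSpec(method="raw"))
        np.testing.assert_array_equal(out.absorbance, spectra.absorbance)

    def test_zero_norm_row_names_sample(self):
        s = make_spectra(np.vstack([np.ones(10), np.zeros(10)]))
        with pytest.raises(ValueError, match="S1"):
            fit_apply_pretreatment(s, PretreatmentSpec(method="normalization"))

    def test_zero_sd_row_names_sample(self):
        s = make_spectra(np.vstack([np.linspace(0, 1, 10), np.full(10, 0.3)]))
        with pytest.raises(ValueError, match="S1"):
            fit_apply_pretreatment(s, PretreatmentSpec(method="snv"))


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        # window-11 order-2 SG leaves any quadratic in column index untouched
        j = np.arange(80, dtype=float)
        A = np.vstack([0.5 + 0.02 * j - 3e-4 * j**2, 1.0 - 0.01 * j + 1e-4 * j**2])
        s = make_spectra(A)
        out, _ = fit_apply_pretreatment(s, PretreatmentSpec(method="sg", window=11, polyorder=2))
        np.testing.assert_allclose(out.absorbance, A, atol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PretreatmentSpec(method="sg", window=10)

    def test_derivative_kills_constants(self, spectra):
        out, _ = fit_apply_pretreatment(
            spectra, PretreatmentSpec(method="sg", window=11, polyorder=2, deriv=1)
        )
        flat = make_spectra(np.full((2, 60), 0.7))
        dflat, _ = fit_apply_pretreatment(
            flat, PretreatmentSpec(method="sg", window=11, polyorder=2, deriv=1)
        )
        np.testing.assert_allclose(dflat.absorbance, 0, atol=1e-12)


class TestMSC:
    def test_rows_equal_to_reference_unchanged(self):
        base = np.sin(np.linspace(0, 3, 40)) + 2
        A = np.tile(base, (4, 1))
        out, spec = fit_apply_pretreatment(make_spectra(A), PretreatmentSpec(method="msc"))
        np.testing.assert_allclose(out.absorbance, A, rtol=1e-10)
        np.testing.assert_allclose(spec.msc_reference, base, rtol=1e-12)

    def test_removes_multiplicative_and_additive_scatter(self, rng):
        base = np.sin(np.linspace(0, 3, 40)) + 2
        slopes = rng.uniform(0.5, 2.0, 6)
        offsets = rng.uniform(-0.3, 0.3, 6)
        A = slopes[:, None] * base + offsets[:, None]
        out, _ = fit_apply_pretreatment(make_spectra(A), PretreatmentSpec(method="msc"))
        # all rows collapse onto (nearly) the same corrected spectrum
        assert np.ptp(out.absorbance, axis=0).max() < 1e-8

    def test_calibration_fitted_state_reapplies_identically(self, spectra):
        out_fit, fitted = fit_apply_pretreatment(spectra, PretreatmentSpec(method="msc"), fit=True)
        out_apply, _ = fit_apply_pretreatment(spectra, fitted, fit=False)
        np.testing.assert_array_equal(out_fit.absorbance, out_apply.absorbance)

    def test_unfitted_application_rejected(self, spectra):
        with pytest.raises(ValueError, match="before fitting"):
            fit_apply_pretreatment(spectra, PretreatmentSpec(method="msc"), fit=False)


class TestSubtractVial:
    def test_zero_vial_is_identity(self, spectra):
        vial = spectra.with_absorbance(np.zeros_like(spectra.absorbance),
                                       mode=AcquisitionMode.EMPTY_VIAL)
        out = subtract_vial(spectra, vial)
        np.testing.assert_array_equal(out.absorbance, spectra.absorbance)
        assert out.mode == AcquisitionMode.DIFFERENCE

    def test_sample_equals_vial_gives_zero(self, spectra):
        out = subtract_vial(spectra, spectra)
        np.testing.assert_array_equal(out.absorbance, 0.0)

    def test_difference_recovers_scaled_mixture(self):
        """Noiseless generator algebra: difference == path_ratio x mixture."""
        cfg = noiseless_config()
        b = generate_dataset(cfg, seed=13)
        profiles = generate_pure_components(cfg)
        truth = b.truth
        mixture = (
            profiles["water"][None, :]
            + truth["true_matrix"].to_numpy()[:, None] * profiles["matrix"][None, :]
            + sum(
                truth[f"true_{k}"].to_numpy()[:, None] * profiles[k][None, :]
                for k in ("epigoitrin", "geniposide", "baicalin")
            )
        )
        diff = subtract_vial(b.spectra_through_vial, b.spectra_empty_vial)
        np.testing.assert_allclose(diff.absorbance, cfg.path_ratio * mixture, atol=1e-10)

    def test_id_mismatch_rejected(self, spectra):
        vial = SpectraSet(
            sample_ids=tuple(f"V{i}" for i in range(spectra.n_samples)),
            wavenumbers=spectra.wavenumbers,
            absorbance=np.zeros_like(spectra.absorbance),
            mode=AcquisitionMode.EMPTY_VIAL,
        )
        with pytest.raises(ValueError, match="id mismatch"):
            subtract_vial(spectra, vial)

    def test_grid_mismatch_rejected(self, spectra):
        vial = SpectraSet(
            sample_ids=spectra.sample_ids,
            wavenumbers=default_grid(spectra.n_vars, 9000, 4500),
            absorbance=np.zeros_like(spectra.absorbance),
            mode=AcquisitionMode.EMPTY_VIAL,
        )
        with pytest.raises(ValueError, match="grid"):
            subtract_vial(spectra, vial)
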