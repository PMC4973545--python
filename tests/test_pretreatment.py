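import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscal.pretreatment import (
    MATH_TREATMENTS,
    SCATTER_METHODS,
    PretreatmentSpec,
    apply_pretreatment,
    build_grid,
    gap_segment_derivative,
    parse_treatment_code,
    reduced_grid,
    scatter_correct,
)
from nirscal.spectra_io import SpectraSet


class TestTreatmentCodes:
    def test_example_code_parses(self):
        spec = parse_treatment_code("2,4,4,1")
        assert (spec.derivative_order, spec.gap, spec.segment1, spec.segment2) == (2, 4, 4, 1)

    def test_raw_code(self):
        assert parse_treatment_code("0,0,1,1").is_raw

    @pytest.mark.parametrize("code", ["3,2,2,1", "1,0,4,1", "2,4,0,1", "2,4", "a,b,c,d"])
    def test_invalid_codes_rejected(self, code):
        with pytest.raises(ValueError):
            parse_treatment_code(code)

    def test_grid_is_77_unique_combinations(self):
        grid = build_grid()
        assert len(grid) == 77
        labels = {s.label for s in grid}
        assert len(labels) == 77
        assert "2,12,12,1+SNVD" in labels
        assert len(SCATTER_METHODS) == 7 and len(MATH_TREATMENTS) == 11

    def test_reduced_grid_is_subset_of_full(self):
        full = {s.label for s in build_grid()}
        red = [s.label for s in reduced_grid()]
        assert len(red) == 20 and set(red) <= full


class TestScatterCorrection:
    def test_snv_of_012(self):
        out, _ = scatter_correct(np.array([[0.0, 1.0, 2.0]]), "SNV")
        np.testing.assert_allclose(out[0], [-1.0, 0.0, 1.0])

    def test_snv_rows_standardised(self, rng):
        X = rng.random((10, 40)) + rng.random((10, 1)) * 3
        out, _ = scatter_correct(X, "SNV")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_snv_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row"):
            scatter_correct(np.ones((1, 10)), "SNV")

    def test_detrend_annihilates_quadratics(self, rng, toy_grid):
        X = rng.random((5, toy_grid.size))
        coefs = rng.random((5, 3))
        quad = (
            coefs[:, [0]]
            + coefs[:, [1]] * toy_grid
            + coefs[:, [2]] * toy_grid**2 / 1e3
        )
        base, _ = scatter_correct(X, "Detrend", wavelengths=toy_grid)
        plus, _ = scatter_correct(X + quad, "Detrend", wavelengths=toy_grid)
        np.testing.assert_allclose(plus, base, atol=1e-8)

    def test_smsc_recovers_affine_distortion(self, rng):
        ref_row = np.sin(np.linspace(0, 3, 50)) + 2
        X = np.vstack([a + b * ref_row for a, b in [(0.1, 1.2), (-0.2, 0.8), (0.0, 1.0)]])
        out, ref = scatter_correct(X, "SMSC", fit=True)
        # fitting makes the reference the column mean; rows that are affine in
        # it map exactly back onto it
        np.testing.assert_allclose(out, np.tile(ref.mean_spectrum, (3, 1)), atol=1e-10)

    def test_wmsc_matches_smsc_under_uniform_weights(self, rng):
        X = rng.random((6, 30)) * 0.2 + np.linspace(0.3, 0.8, 30)
        smsc, _ = scatter_correct(X, "SMSC", fit=True)
        _, ref = scatter_correct(X, "WMSC", fit=True)
        ref.weights = np.ones_like(ref.weights)
        wmsc, _ = scatter_correct(X, "WMSC", reference=ref)
        np.testing.assert_allclose(wmsc, smsc, atol=1e-10)

    def test_imsc_returns_reference_scale(self, rng):
        ref_row = np.linspace(0.2, 0.9, 40)
        X = np.vstack([0.05 + 1.3 * ref_row, -0.02 + 0.7 * ref_row])
        out, reference = scatter_correct(X, "IMSC", fit=True)
        # exact affine rows regress perfectly: a' + b'x reproduces the reference
        np.testing.assert_allclose(out, np.tile(reference.mean_spectrum, (2, 1)), atol=1e-10)

    def test_msc_apply_mode_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            scatter_correct(np.random.default_rng(0).random((2, 10)), "SMSC")

    def test_smsc_then_snv_collapses_scatter_copies(self, rng):
        base = 0.3 + 0.5 * np.exp(-0.5 * ((np.arange(80) - 40) / 10.0) ** 2)
        mult = 1 + rng.normal(0, 0.1, size=(12, 1))
        add = rng.normal(0, 0.05, size=(12, 1))
        X = mult * base + add
        corrected, _ = scatter_correct(X, "SMSC", fit=True)
        snv, _ = scatter_correct(corrected, "SNV")
        spread = np.ptp(snv, axis=0).max()
        assert spread < 1e-8  # pure affine scatter is removed exactly


class TestGapSegmentDerivative:
    def test_second_derivative_kills_linear_ramp(self):
        x = 3.0 + 0.25 * np.arange(50.0)
        y, _ = gap_segment_derivative(x, 2, 4, 4, 1)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_second_derivative_of_squares_is_2g_squared(self):
        x = np.arange(60.0) ** 2
        y, offset = gap_segment_derivative(x, 2, 4, 1, 1)
        np.testing.assert_allclose(y, 32.0, atol=1e-9)
        assert offset == 4

    def test_first_derivative_of_ramp_is_2g(self):
        x = np.arange(40.0)
        y, offset = gap_segment_derivative(x, 1, 3, 1, 1)
        np.testing.assert_allclose(y, 6.0, atol=1e-10)
        assert offset == 3

    def test_output_length_matches_truncation(self):
        x = np.zeros(100)
        y, offset = gap_segment_derivative(x, 2, 4, 4, 1)
        assert y.shape[1] == 100 - 3 - 8
        assert offset == 1 + 4

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            gap_segment_derivative(np.zeros(10), 2, 4, 4, 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        d=st.sampled_from([0, 1, 2]),
        g=st.integers(1, 5),
        s1=st.sampled_from([1, 3, 4]),
    )
    def test_linearity(self, seed, d, g, s1):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 60))
        a, b = r.normal(size=2)
        lhs, _ = gap_segment_derivative(a * x + b * y, d, g, s1, 1)
        fx, _ = gap_segment_derivative(x, d, g, s1, 1)
        fy, _ = gap_segment_derivative(y, d, g, s1, 1)
        np.testing.assert_allclose(lhs, a * fx + b * fy, atol=1e-10)


class TestApplyPretreatment:
    def test_raw_spec_is_identity(self, toy_spectra):
        out = apply_pretreatment(toy_spectra, PretreatmentSpec(0, 0, 1, 1))
        np.testing.assert_allclose(out.absorbance, toy_spectra.absorbance)
        np.testing.assert_allclose(out.wavelengths, toy_spectra.wavelengths)

    def test_fitted_spec_is_deterministic(self, toy_spectra):
        spec = PretreatmentSpec(1, 2, 2, 1, scatter_method="SMSC")
        first = apply_pretreatment(toy_spectra, spec, fit=True)
        second = apply_pretreatment(toy_spectra, spec, fit=False)
        np.testing.assert_allclose(first.absorbance, second.absorbance)

    def test_retained_grid_is_reported(self, toy_spectra):
        spec = PretreatmentSpec(2, 4, 4, 1, scatter_method="SNV")
        out = apply_pretreatment(toy_spectra, spec)
        assert out.n_wavelengths == toy_spectra.n_wavelengths - 3 - 8
        assert out.wavelengths[0] == toy_spectra.wavelengths[1 + 4]

    def test_snvd_reduces_between_row_variance_on_scatter_data(self, rng, toy_grid):
        # scatter-perturbed copies of one underlying spectrum: derivative alone
        # keeps the multiplicative spread, derivative+SNVD collapses it
        base = 0.4 + 0.3 * np.exp(-0.5 * ((toy_grid - 1160) / 15.0) ** 2)
        mult = 1 + rng.normal(0, 0.1, size=(15, 1))
        add = rng.normal(0, 0.05, size=(15, 1))
        s = SpectraSet(toy_grid, mult * base + add, [f"s{i}" for i in range(15)])
        plain = apply_pretreatment(s, PretreatmentSpec(2, 4, 4, 1))
        snvd = apply_pretreatment(s, PretreatmentSpec(2, 4, 4, 1, scatter_method="SNVD"))
        assert snvd.absorbance.var(axis=0).mean() < plain.absorbance.var(axis=0).mean()
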