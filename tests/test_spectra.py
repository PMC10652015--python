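"""Core spectral operations: extraction, derivative, readout selection."""

import numpy as np
import pytest

from synchrofluor.errors import DomainError
from synchrofluor.simulate import gaussian, simulate_eem
from synchrofluor.spectra import (
    AnalyticalWavelengths,
    DerivativeSpectrum,
    ExcitationEmissionMatrix,
    SynchronousSpectrum,
    WavelengthGrid,
    amplitude_at,
    extract_synchronous,
    find_zero_crossings,
    resolution_score,
    savgol_first_derivative,
    select_analytical_wavelengths,
)

EX = WavelengthGrid(240.0, 340.0, 1.0)
EM = WavelengthGrid(300.0, 600.0, 1.0)


def make_eem(fn):
    xx, yy = np.meshgrid(EX.values, EM.values, indexing="ij")
    return ExcitationEmissionMatrix(EX, EM, fn(xx, yy))


class TestWavelengthGrid:
    def test_values_are_uniform_and_inclusive(self):
        g = WavelengthGrid(290.0, 600.0, 1.0)
        assert len(g) == 311
        assert g.values[0] == 290.0 and g.values[-1] == 600.0

    @pytest.mark.parametrize("args", [(400, 300, 1.0), (300, 400, -1.0), (300, 400, 0.0)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            WavelengthGrid(*args)

    def test_from_values_requires_uniform_increasing(self):
        with pytest.raises(ValueError):
            WavelengthGrid.from_values(np.array([1.0, 2.0, 1.5]))
        with pytest.raises(ValueError):
            WavelengthGrid.from_values(np.array([1.0, 2.0, 4.0]))


class TestExtractSynchronous:
    def test_constant_eem_gives_constant_spectrum(self):
        eem = make_eem(lambda x, y: np.ones_like(x))
        s = extract_synchronous(eem, 50.0)
        assert np.allclose(s.intensity, 1.0)
        # valid emission range: λem − 50 must lie in [240, 340]
        assert s.em_grid.start == 300.0 and s.em_grid.values[-1] == 390.0

    def test_linearity_under_eem_addition(self):
        a = make_eem(lambda x, y: gaussian(x, 285, 20) * gaussian(y, 455, 25))
        b = make_eem(lambda x, y: gaussian(x, 300, 15) * gaussian(y, 380, 30))
        both = ExcitationEmissionMatrix(EX, EM, a.intensity + b.intensity)
        sa, sb, sab = (extract_synchronous(e, 50.0) for e in (a, b, both))
        assert np.allclose(sab.intensity, sa.intensity + sb.intensity)

    def test_gaussian_diagonal_matches_bruteforce_argmax(self):
        # oracle: evaluate G(λ−50; 285, 20)·G(λ; 455, 25) directly on the grid
        eem = make_eem(lambda x, y: gaussian(x, 285, 20) * gaussian(y, 455, 25))
        s = extract_synchronous(eem, 50.0)
        lam = s.em_grid.values
        brute = gaussian(lam - 50.0, 285, 20) * gaussian(lam, 455, 25)
        assert np.allclose(s.intensity, brute, atol=1e-12)
        assert lam[np.argmax(s.intensity)] == lam[np.argmax(brute)]

    def test_diagonal_outside_domain_raises(self):
        eem = make_eem(lambda x, y: np.ones_like(x))
        with pytest.raises(DomainError):
            extract_synchronous(eem, 400.0)

    def test_nonpositive_offset_rejected(self):
        eem = make_eem(lambda x, y: np.ones_like(x))
        with pytest.raises(ValueError):
            extract_synchronous(eem, -5.0)

    def test_offgrid_offset_interpolates_excitation_axis(self):
        # Δλ = 50.5 lands midway between excitation grid points: the
        # extracted value must be the mean of the two bracketing columns
        eem = make_eem(lambda x, y: x.astype(float))
        s = extract_synchronous(eem, 50.5)
        assert np.allclose(s.intensity, s.em_grid.values - 50.5)


class TestSavgolDerivative:
    def grid_spec(self, y, grid=None):
        grid = grid or WavelengthGrid(300.0, 600.0, 1.0)
        return SynchronousSpectrum(50.0, grid, y)

    def test_constant_spectrum_has_zero_derivative(self):
        s = self.grid_spec(np.full(301, 7.3))
        d = savgol_first_derivative(s)
        assert np.allclose(d.d_intensity, 0.0, atol=1e-12)

    def test_linear_ramp_recovers_slope_everywhere(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        s = self.grid_spec(4.2 * g.values - 100.0, g)
        d = savgol_first_derivative(s)
        # exact for polynomials of the fit order, including the edges
        assert np.allclose(d.d_intensity, 4.2, atol=1e-9)

    def test_gaussian_matches_analytic_derivative(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        y = gaussian(g.values, 455.0, 25.0)
        d = savgol_first_derivative(self.grid_spec(y, g))
        analytic = -(g.values - 455.0) / 25.0**2 * y
        err = np.max(np.abs(d.d_intensity - analytic))
        assert err < 1e-3 * np.max(np.abs(analytic))

    def test_spectrum_shorter_than_window_rejected(self):
        s = SynchronousSpectrum(50.0, WavelengthGrid(300, 305, 1.0), np.ones(6))
        with pytest.raises(ValueError):
            savgol_first_derivative(s, window_points=9)

    def test_half_nm_grid_scales_by_step(self):
        g = WavelengthGrid(300.0, 400.0, 0.5)
        s = self.grid_spec(2.0 * g.values, g)
        d = savgol_first_derivative(s)
        assert np.allclose(d.d_intensity, 2.0, atol=1e-9)


class TestAmplitudeAt:
    def dspec(self, vals, start=400.0):
        g = WavelengthGrid(start, start + len(vals) - 1, 1.0)
        return DerivativeSpectrum(g, np.asarray(vals, dtype=float))

    def test_grid_point_returns_stored_value(self):
        d = self.dspec([1.0, -2.5, 3.0] + [0.0] * 6)
        assert amplitude_at(d, 401.0) == -2.5

    def test_midpoint_linear_interpolation(self):
        d = self.dspec([2.0, 4.0] + [0.0] * 7)
        assert amplitude_at(d, 400.5) == pytest.approx(3.0)

    def test_gaussian_inflection_matches_closed_form(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        y = gaussian(g.values, 455.0, 25.0)
        d = savgol_first_derivative(SynchronousSpectrum(50.0, g, y))
        # at λ = c − w the analytic first derivative is (1/w)·e^(−1/2)
        expected = np.exp(-0.5) / 25.0
        assert amplitude_at(d, 430.0) == pytest.approx(expected, rel=1e-3)

    def test_outside_grid_raises(self):
        d = self.dspec([0.0] * 9)
        with pytest.raises(DomainError):
            amplitude_at(d, 350.0)


class TestZeroCrossings:
    def test_strictly_positive_derivative_has_none(self):
        g = WavelengthGrid(300.0, 400.0, 1.0)
        d = DerivativeSpectrum(g, np.ones(len(g)))
        assert find_zero_crossings(d) == []

    def test_symmetric_band_crosses_at_its_centre(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        y = gaussian(g.values, 455.0, 25.0)
        d = savgol_first_derivative(SynchronousSpectrum(50.0, g, y))
        crossings = find_zero_crossings(d, min_flank=1e-6)
        assert len(crossings) == 1
        assert abs(crossings[0] - 455.0) <= 0.5

    def test_matches_bruteforce_sign_scan_on_random_bands(self):
        rng = np.random.default_rng(42)
        g = WavelengthGrid(300.0, 600.0, 1.0)
        y = sum(
            rng.uniform(0.5, 2.0) * gaussian(g.values, c, w)
            for c, w in zip(rng.uniform(330, 570, 3), rng.uniform(8, 30, 3))
        )
        d = savgol_first_derivative(SynchronousSpectrum(50.0, g, y))
        found = find_zero_crossings(d)
        # oracle: exhaustive scan for sign changes with linear interpolation
        dv, lam = d.d_intensity, g.values
        expected = [
            lam[i] - dv[i] / (dv[i + 1] - dv[i])
            for i in range(len(dv) - 1)
            if dv[i] * dv[i + 1] < 0
        ]
        assert np.allclose(found, expected)

    def test_noise_guard_suppresses_isolated_wiggles(self):
        g = WavelengthGrid(300.0, 320.0, 1.0)
        wiggle = 1e-6 * np.sin(np.arange(len(g)) * 2.5)
        d = DerivativeSpectrum(g, wiggle)
        assert find_zero_crossings(d, min_flank=0.1) == []
        # a genuine crossing with strong flanks survives the same guard
        strong = np.concatenate([np.linspace(1, -1, 11), -np.ones(10)])
        kept = find_zero_crossings(DerivativeSpectrum(g, strong), min_flank=0.1)
        assert kept == [305.0]


class TestSelectAnalyticalWavelengths:
    def test_disjoint_support_returns_global_maxima(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        a = np.where(g.values < 440, np.sin((g.values - 300) / 20.0), 0.0)
        b = np.where(g.values > 470, np.cos((g.values - 470) / 15.0), 0.0)
        da, db = DerivativeSpectrum(g, a), DerivativeSpectrum(g, b)
        wl = select_analytical_wavelengths(da, db)
        assert abs(a[int(wl.lambda_A - 300)]) == pytest.approx(np.max(np.abs(a)))
        assert abs(b[int(wl.lambda_B - 300)]) == pytest.approx(np.max(np.abs(b)))

    def test_default_complexed_models_select_published_readouts(self, models):
        hl, hm = models
        da = savgol_first_derivative(extract_synchronous(simulate_eem([(hl, 100.0)]), 50.0))
        db = savgol_first_derivative(extract_synchronous(simulate_eem([(hm, 100.0)]), 50.0))
        wl = select_analytical_wavelengths(da, db)
        assert wl.lambda_A == pytest.approx(419.0, abs=2.0)
        assert wl.lambda_B == pytest.approx(456.0, abs=2.0)
        assert not wl.fallback_A and not wl.fallback_B

    def test_agrees_with_bruteforce_over_crossing_candidates(self):
        rng = np.random.default_rng(7)
        g = WavelengthGrid(300.0, 600.0, 1.0)

        def band_pair():
            y = sum(
                rng.uniform(0.5, 2.0) * gaussian(g.values, c, w)
                for c, w in zip(rng.uniform(340, 560, 2), rng.uniform(10, 30, 2))
            )
            return savgol_first_derivative(SynchronousSpectrum(50.0, g, y))

        da, db = band_pair(), band_pair()
        wl = select_analytical_wavelengths(da, db)
        # oracle: evaluate |analyte| at every interferent crossing directly
        def brute(analyte, interferent):
            cs = find_zero_crossings(
                interferent, 1e-9 * np.max(np.abs(interferent.d_intensity))
            )
            return max(cs, key=lambda c: abs(amplitude_at(analyte, c)))

        assert wl.lambda_A == pytest.approx(brute(da, db))
        assert wl.lambda_B == pytest.approx(brute(db, da))

    def test_invariant_under_joint_rescaling(self, models):
        hl, hm = models
        da = savgol_first_derivative(extract_synchronous(simulate_eem([(hl, 100.0)]), 50.0))
        db = savgol_first_derivative(extract_synchronous(simulate_eem([(hm, 100.0)]), 50.0))
        wl = select_analytical_wavelengths(da, db)
        da2 = DerivativeSpectrum(da.em_grid, 37.5 * da.d_intensity)
        db2 = DerivativeSpectrum(db.em_grid, 37.5 * db.d_intensity)
        wl2 = select_analytical_wavelengths(da2, db2)
        assert wl2.lambda_A == wl.lambda_A and wl2.lambda_B == wl.lambda_B

    def test_mismatched_grids_rejected(self):
        d1 = DerivativeSpectrum(WavelengthGrid(300, 400, 1.0), np.zeros(101))
        d2 = DerivativeSpectrum(WavelengthGrid(300, 401, 1.0), np.zeros(102))
        with pytest.raises(ValueError):
            select_analytical_wavelengths(d1, d2)


class TestResolutionScore:
    def setup_pair(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        a = gaussian(g.values, 400.0, 20.0) - gaussian(g.values, 440.0, 20.0)
        return g, DerivativeSpectrum(g, a)

    def test_zero_interferent_at_readouts_scores_large_but_finite(self):
        g = WavelengthGrid(300.0, 600.0, 1.0)
        a = np.where(g.values < 440, gaussian(g.values, 380.0, 15.0), 0.0)
        b = np.where(g.values > 470, gaussian(g.values, 520.0, 15.0), 0.0)
        da, db = DerivativeSpectrum(g, a), DerivativeSpectrum(g, b)
        # readouts where each analyte peaks and the other is identically zero
        wl = AnalyticalWavelengths(380.0, 520.0)
        score = resolution_score(da, db, wl, eps_rel=1e-3)
        assert np.isfinite(score) and score > 100.0

    def test_identical_spectra_score_near_one(self):
        g, da = self.setup_pair()
        db = DerivativeSpectrum(g, da.d_intensity.copy())
        wl = AnalyticalWavelengths(400.0, 440.0)
        assert resolution_score(da, db, wl) == pytest.approx(1.0, rel=1e-2)

    def test_scale_invariance(self, models):
        hl, hm = models
        da = savgol_first_derivative(extract_synchronous(simulate_eem([(hl, 100.0)]), 50.0))
        db = savgol_first_derivative(extract_synchronous(simulate_eem([(hm, 100.0)]), 50.0))
        wl = select_analytical_wavelengths(da, db)
        s1 = resolution_score(da, db, wl)
        da2 = DerivativeSpectrum(da.em_grid, 1234.5 * da.d_intensity)
        db2 = DerivativeSpectrum(db.em_grid, 1234.5 * db.d_intensity)
        assert resolution_score(da2, db2, wl) == pytest.approx(s1, rel=1e-12)
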