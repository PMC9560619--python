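"""Spatial rate profiles: rings, gradients, logistic fits."""

import numpy as np
import pytest

from wpgap.domain import build_disk
from wpgap.profiles import (LogisticParams, ModulatorModel, RingModulator,
                            fit_logistic, gaussian_ring, logistic,
                            modulated_rate, representative_gradient_profiles,
                            simulate_gradient, spatial_rate_profiles)


class TestGaussianRing:
    def test_peak_at_center_radius(self, disk64):
        mod = RingModulator(center=2.0, variance=0.04, amplitude=3.0)
        M = gaussian_ring(disk64, mod)
        peak_r = disk64.radius_grid().ravel()[np.argmax(M.ravel())]
        dr = disk64.R / disk64.shape[1]
        assert abs(peak_r - 2.0) <= dr
        # cell-centered grid: the nearest node sits within dr/2 of the peak
        assert M.max() == pytest.approx(3.0, rel=0.02)

    def test_zero_amplitude(self, disk64):
        M = gaussian_ring(disk64, RingModulator(amplitude=0.0))
        assert np.all(M == 0)

    def test_inverted_ring_has_trough(self, disk64):
        M = gaussian_ring(disk64, RingModulator(orientation="inverted"))
        trough_r = disk64.radius_grid().ravel()[np.argmin(M.ravel())]
        assert abs(trough_r - 2.0) <= disk64.R / disk64.shape[1]
        assert M.max() <= 1.0

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            RingModulator(variance=0.0)


class TestModulatedRate:
    def test_zero_coupling_is_constant(self, disk64):
        M = gaussian_ring(disk64, RingModulator())
        out = modulated_rate(7.0, 0.0, "+", M)
        assert np.all(out == 7.0)

    def test_positive_coupling_peaks_on_ring(self, disk64):
        M = gaussian_ring(disk64, RingModulator())
        out = modulated_rate(2.0, 5.0, "+", M)
        assert out.max() == pytest.approx(2.0 + 5.0 * M.max(), rel=1e-12)

    def test_omega_linearity(self, disk64):
        M = gaussian_ring(disk64, RingModulator())
        plus = modulated_rate(10.0, 3.0, "+", M)
        minus = modulated_rate(10.0, 3.0, "-", M)
        np.testing.assert_allclose(plus + minus, 20.0, rtol=1e-12)

    def test_negative_rate_rejected(self, disk64):
        M = gaussian_ring(disk64, RingModulator())
        with pytest.raises(ValueError):
            modulated_rate(1.0, 5.0, "-", M)


class TestSimulateGradient:
    def test_zero_diffusion_limit_is_k_over_delta(self, disk64):
        mod = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                             delta_x=0.75, D_x=0.0)
        X = simulate_gradient(mod, disk64)
        from wpgap.profiles import step_activation
        np.testing.assert_allclose(X, step_activation(disk64.r, mod) / 0.75,
                                   rtol=1e-10)

    def test_uniform_source_gives_uniform_profile(self, disk64):
        mod = ModulatorModel(k_disk=0.3, k_basal=0.3, mu_F=2.0,
                             delta_x=0.75, D_x=1.0)
        X = simulate_gradient(mod, disk64)
        np.testing.assert_allclose(X, 0.4, rtol=1e-9)

    def test_diffusion_monotonically_flattens_gradient(self, disk64):
        slopes, contrasts = [], []
        for D in (1e-3, 1e-2, 1e-1, 1.0, 10.0):
            mod = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                                 delta_x=0.75, D_x=D)
            X = simulate_gradient(mod, disk64)
            slopes.append(np.max(np.abs(np.diff(X))))
            contrasts.append(X[0] - X[-1])
        assert np.all(np.diff(slopes) < 0)
        assert np.all(np.diff(contrasts) < 0)

    def test_steady_profile_bounded_by_extreme_levels(self, disk64):
        mod = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                             delta_x=0.75, D_x=0.5)
        X = simulate_gradient(mod, disk64)
        assert np.all(X >= 0.075 / 0.75 - 1e-9)
        assert np.all(X <= 1.5 / 0.75 + 1e-9)

    def test_finite_horizon_approaches_steady_state(self, disk64):
        mod = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                             delta_x=0.75, D_x=0.1)
        X40 = simulate_gradient(mod, disk64, t_final=40.0)
        X_inf = simulate_gradient(mod, disk64)
        assert np.max(np.abs(X40 - X_inf)) < 1e-6 * X_inf.max()


class TestLogisticFit:
    def test_exact_recovery_of_synthetic_parameters(self, disk64):
        r = disk64.r
        y = logistic(r, beta=1.0, alpha=4.0, km=2.0, r0=2.0)
        fit = fit_logistic(r, y)
        assert fit.identifiable
        assert fit.params.beta == pytest.approx(1.0, abs=1e-4)
        assert fit.params.alpha == pytest.approx(4.0, abs=1e-4)
        assert fit.params.km == pytest.approx(2.0, abs=1e-4)
        assert fit.params.r0 == pytest.approx(2.0, abs=1e-4)

    def test_constant_profile_flagged_unidentifiable(self, disk64):
        fit = fit_logistic(disk64.r, np.full(disk64.r.size, 3.7))
        assert not fit.identifiable
        assert fit.params.alpha == pytest.approx(0.0, abs=1e-12)
        assert fit.params.beta == pytest.approx(3.7)

    def test_fits_simulated_gradient_within_two_percent(self, disk64):
        mod = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                             delta_x=0.75, D_x=0.1)
        X = simulate_gradient(mod, disk64)
        fit = fit_logistic(disk64.r, X)
        assert fit.rms < 0.02 * (X.max() - X.min())

    def test_resampling_density_invariance(self):
        coarse = build_disk(R=4.0, n_phi=8, n_r=64)
        fine = build_disk(R=4.0, n_phi=8, n_r=128)
        y_c = logistic(coarse.r, 0.5, 3.0, 1.7, 2.1) \
            + 0.01 * np.sin(coarse.r * 20)
        y_f = logistic(fine.r, 0.5, 3.0, 1.7, 2.1) \
            + 0.01 * np.sin(fine.r * 20)
        f_c = fit_logistic(coarse.r, y_c).params
        f_f = fit_logistic(fine.r, y_f).params
        for a, b in ((f_c.beta, f_f.beta), (f_c.alpha, f_f.alpha),
                     (f_c.km, f_f.km), (f_c.r0, f_f.r0)):
            assert abs(a - b) < 0.01 * max(abs(a), abs(b))

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(5.0), np.arange(5.0))


class TestSpatialRateProfiles:
    def test_far_field_asymptote_is_the_minimum(self, disk64):
        gp, cp = representative_gradient_profiles(r0=2.0)
        r = np.array([50.0])
        assert gp(r)[0] == pytest.approx(0.005, rel=1e-6)
        assert cp(r)[0] == pytest.approx(0.005, rel=1e-6)

    def test_disk_center_approaches_maximum(self):
        gp, _ = representative_gradient_profiles(r0=2.0)
        assert gp(np.array([0.0]))[0] == pytest.approx(
            9.6, rel=np.exp(-2.04 * 2.0))

    def test_ratio_peaks_just_outside_disk_edge(self, disk64):
        gp, cp = representative_gradient_profiles(r0=2.0)
        r = np.linspace(0, 4, 4001)
        ratio = gp(r) / cp(r)
        r_star = r[np.argmax(ratio)]
        assert 2.0 < r_star < 3.0

    def test_hole_profiles_mirror_disk_profiles(self, disk64):
        gp_d, cp_d = representative_gradient_profiles(r0=2.0)
        gp_h, cp_h = representative_gradient_profiles(r0=2.0, hole=True)
        r = np.linspace(0, 4, 33)
        np.testing.assert_allclose(gp_h(r), gp_d(4.0 - r), rtol=1e-9)
        np.testing.assert_allclose(cp_h(r), cp_d(4.0 - r), rtol=1e-9)

    def test_grid_profiles_are_radial(self, disk64):
        gp, cp = representative_gradient_profiles(r0=2.0)
        gam, cc, ratio = spatial_rate_profiles(gp, cp, disk64)
        assert gam.shape == disk64.shape
        assert np.ptp(gam, axis=0).max() < 1e-12
        np.testing.assert_allclose(ratio, gam / cc)

    def test_max_below_min_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams.from_min_max(1.0, 0.5, 2.0, 2.0)


class TestLogisticFitProperty:
    """Property: the constrained fit reproduces any noiseless logistic."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(beta=st.floats(0.01, 5.0), alpha=st.floats(0.1, 20.0),
           km=st.floats(0.5, 6.0), r0=st.floats(0.5, 3.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fit_reproduces_noiseless_curves(self, beta, alpha, km, r0):
        r = np.linspace(0.0, 4.0, 96)
        y = logistic(r, beta, alpha, km, r0)
        fit = fit_logistic(r, y)
        assert fit.rms < 1e-5 * alpha
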