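"""Integrator contracts: domains, conservation, diffusion accuracy,
ODE limit, symmetry and coupled modulators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from wpgap.domain import build_disk, build_domain, build_rectangle
from wpgap.model import FieldState, hill, homogeneous_steady_state
from wpgap.params import WPGAPParams
from wpgap.solver import (BlowUpError, Coupling, Modulator,
                          attach_modulators, integrate)
from wpgap.synth import InitSpec, noisy_initial_condition


def _ss_state(params, domain):
    u, v, G, g = homogeneous_steady_state(params)
    return FieldState(*(np.full(domain.shape, x) for x in (u, v, G, g)),
                      domain=domain)


class TestDomains:
    def test_quadrature_sums_to_area(self):
        disk = build_disk(R=4.0, n_phi=256, n_r=128)
        assert disk.area == pytest.approx(np.pi * 16.0, abs=1e-10)
        rect = build_rectangle(Lx=5.0, Ly=3.0, n_x=64, n_y=32)
        assert rect.area == pytest.approx(15.0, abs=1e-10)

    def test_polar_nodes(self):
        disk = build_disk(R=4.0, n_phi=256, n_r=128)
        assert disk.phi[0] == 0.0 and disk.phi[-1] < 2 * np.pi
        assert disk.phi.size == 256 and disk.r.size == 128
        assert 0 < disk.r[0] and disk.r[-1] <= 4.0

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            build_disk(R=-1.0)
        with pytest.raises(ValueError):
            build_rectangle(n_x=0)
        with pytest.raises(ValueError):
            build_domain("spherical")

    def test_build_domain_dispatch(self):
        assert build_domain("polar-disk", R=2.0, n_phi=16, n_r=8).is_polar
        assert not build_domain("cartesian", n_x=8, n_y=8).is_polar


class TestDiffusionAccuracy:
    def test_cartesian_mode_decay_matches_heat_equation(self):
        dom = build_rectangle(Lx=5.0, Ly=5.0, n_x=64, n_y=64)
        p = WPGAPParams(b=0, gamma=0, sigma=0, c=0, d=0, e=0)
        kx = 2 * np.pi / 5.0
        u0 = 100 + np.cos(kx * dom.x)[:, None] * np.ones(64)[None, :]
        st = FieldState(u0, np.full(dom.shape, 708.0),
                        np.full(dom.shape, 5.0), np.full(dom.shape, 5.0),
                        domain=dom)
        traj = integrate(st, p, dom, dt=0.025, t_final=2.0)
        amp = [(s.u.max() - s.u.min()) / 2 for s in traj.states]
        rate = -np.log(amp[-1] / amp[0]) / 2.0
        assert rate == pytest.approx(p.Du * kx ** 2, rel=0.01)
        assert traj.conservation_drift() < 1e-8

    def test_polar_pure_diffusion_relaxes_to_uniform(self, disk64):
        # slowest disk Neumann mode (m=1) decays at D*(1.8412/R)^2; by
        # t=20 with D=4 any initial roughness is below 1e-4 of the mean
        p = WPGAPParams(b=0, gamma=0, sigma=0, c=0, d=0, e=0, Du=4.0,
                        Dv=4.0, DG=4.0, Dg=4.0)
        rng = np.random.default_rng(0)
        u0 = rng.uniform(0, 100, disk64.shape)
        st = FieldState(u0, np.full(disk64.shape, 10.0),
                        np.full(disk64.shape, 5.0),
                        np.full(disk64.shape, 5.0), domain=disk64)
        traj = integrate(st, p, disk64, dt=0.025, t_final=20.0)
        mean0 = disk64.mean(u0)
        assert traj.conservation_drift() < 1e-10
        assert np.ptp(traj.final.u) < 1e-4 * mean0
        assert traj.final.u[0, 0] == pytest.approx(mean0, rel=1e-4)

    def test_zero_diffusion_reduces_to_homogeneous_ode(self, base):
        dom = build_rectangle(Lx=2, Ly=2, n_x=8, n_y=8)
        p = base.replace(Du=0, Dv=0, DG=0, Dg=0)
        st = FieldState(np.full(dom.shape, 50.0), np.full(dom.shape, 758.0),
                        np.full(dom.shape, 5.0), np.full(dom.shape, 5.0),
                        domain=dom)
        traj = integrate(st, p, dom, dt=0.01, t_final=5.0)

        def rhs(_t, y):
            u, G = y
            v, g = p.T - u, p.Tg - G
            return [p.b * v + p.gamma * v * hill(u, p.K, p.n)
                    - p.sigma * u - p.e * G * u,
                    p.c * u * g - p.d * G]

        ref = solve_ivp(rhs, (0, 5), [50, 5], rtol=1e-12, atol=1e-12)
        assert traj.final.u[0, 0] == pytest.approx(ref.y[0, -1], abs=1e-6)
        assert traj.final.G[3, 3] == pytest.approx(ref.y[1, -1], abs=1e-6)


class TestIntegrationContracts:
    def test_conservation_in_patterning_run(self, base, rect64):
        st = noisy_initial_condition(base, rect64, InitSpec(rng_seed=0))
        traj = integrate(st, base, rect64, dt=0.025, t_final=5.0)
        assert traj.conservation_drift() < 1e-5

    def test_radially_symmetric_solution_stays_symmetric(self, disk64):
        p = WPGAPParams(b=2e-3, gamma=5e-3, sigma=0.4, c=5e-3, d=43.0,
                        e=31.3)
        st = _ss_state(p, disk64)
        # radially varying, angle-independent rate profile
        gam = 5e-3 + 9.6 / (1 + np.exp(2.04 * (disk64.radius_grid() - 2.0)))
        traj = integrate(st, p, disk64, dt=0.025, t_final=5.0,
                         profiles={"gamma": gam})
        angular_var = np.ptp(traj.final.u, axis=0).max()
        assert angular_var < 1e-6 * traj.final.u.max()

    def test_snapshot_times_strictly_increase(self, base, rect64):
        st = _ss_state(base, rect64)
        traj = integrate(st, base, rect64, dt=0.025, t_final=3.0,
                         snapshot_every=1.0)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(3.0)

    def test_invalid_dt_raises(self, base, rect64):
        with pytest.raises(ValueError):
            integrate(_ss_state(base, rect64), base, rect64, dt=0.0)

    def test_blowup_reports_failing_time(self, rect64):
        # absurd rates at explicit-step scale guarantee overflow
        p = WPGAPParams(b=1e4, gamma=1e6, sigma=1e-3, c=50.0, d=1e-3,
                        e=1e5)
        st = FieldState(np.full(rect64.shape, 400.0),
                        np.full(rect64.shape, 408.0),
                        np.full(rect64.shape, 5.0),
                        np.full(rect64.shape, 5.0), domain=rect64)
        with pytest.raises(BlowUpError) as exc:
            integrate(st, p, rect64, dt=0.025, t_final=10.0)
        assert 0 < exc.value.t <= 10.0


class TestModulators:
    def test_coupling_validation(self):
        m = Modulator("X", k=1.0, delta=0.5, D=0.1)
        with pytest.raises(ValueError):
            attach_modulators([m], [Coupling("Y", "gamma")])
        with pytest.raises(ValueError):
            attach_modulators([m], [Coupling("X", "zeta")])
        with pytest.raises(ValueError):
            Modulator("X", k=1.0, delta=0.0, D=0.1)

    def test_zero_diffusion_step_source_reaches_k_over_delta(self, disk64):
        from wpgap.profiles import ModulatorModel, step_activation
        mm = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                            delta_x=0.75, D_x=0.0)
        k2d = step_activation(disk64.radius_grid(), mm)
        p = WPGAPParams(b=2e-3, gamma=5e-3, sigma=0.4, c=5e-3, d=43.0,
                        e=31.3)
        ms = attach_modulators([Modulator("X", k=k2d, delta=0.75, D=0.0)],
                               [Coupling("X", "gamma", 0.0, 1.0)])
        st = _ss_state(p, disk64)
        traj = integrate(st, p, disk64, dt=0.025, t_final=40.0,
                         modulator_system=ms)
        X = traj.modulator_states["X"][-1]
        np.testing.assert_allclose(X, k2d / 0.75, atol=1e-10)

    def test_decoupled_modulator_matches_gradient_solver(self, disk64):
        from wpgap.profiles import ModulatorModel, simulate_gradient, \
            step_activation
        mm = ModulatorModel(k_disk=1.5, k_basal=0.075, mu_F=2.0,
                            delta_x=0.75, D_x=0.1)
        k2d = step_activation(disk64.radius_grid(), mm)
        p = WPGAPParams(b=2e-3, gamma=5e-3, sigma=0.4, c=5e-3, d=43.0,
                        e=31.3)
        ms = attach_modulators([Modulator("X", k=k2d, delta=0.75, D=0.1)],
                               [])
        st = _ss_state(p, disk64)
        traj = integrate(st, p, disk64, dt=0.025, t_final=40.0,
                         modulator_system=ms)
        X = traj.modulator_states["X"][-1].mean(axis=0)
        X_ref = simulate_gradient(mm, disk64)
        assert np.max(np.abs(X - X_ref)) < 1e-4 * X_ref.max()
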