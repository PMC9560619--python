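"""Time integration of the WPGAP reaction-diffusion system.

Operator splitting (Strang): the stiff linear diffusion is advanced by an
unconditionally stable scheme, the pointwise reactions by explicit
Runge-Kutta (4th order; 2nd order in the documented ``fast`` mode used for
parameter searches).

Diffusion schemes by geometry:

* rectangle - Fourier collocation in the periodic x direction and a
  cosine (DCT-II) expansion in the no-flux y direction; diffusion is
  advanced with the exact eigenmode propagator exp(-D k^2 dt).
* disk - Fourier collocation in phi; for each angular mode m the radial
  operator (1/r) d/dr (r d/dr) - m^2/r^2 is discretized with conservative
  second-order finite differences on a cell-centered grid (no node at the
  origin, zero-flux faces at r=0 and r=R) and advanced by L-stable
  TR-BDF2 (Crank-Nicolson would leave the stiff near-origin angular
  modes ringing).

Both schemes leave the area-weighted mean of every field invariant, so the
pool totals are conserved to machine precision; the reaction substeps
conserve u+v and G+g pointwise by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np
from scipy import fft as sfft

from .domain import SimDomain
from .model import FieldState, hill, _resolve_rates
from .params import WPGAPParams, RATE_NAMES

__all__ = ["integrate", "Trajectory", "BlowUpError", "Modulator",
           "Coupling", "ModulatorSystem", "attach_modulators"]


class BlowUpError(RuntimeError):
    """Raised when fields become non-finite; carries the failing time."""

    def __init__(self, t: float):
        super().__init__(f"fields became non-finite at t = {t:.4g} s")
        self.t = t


# --------------------------------------------------------------------------
# diffusion operators
# --------------------------------------------------------------------------

class _CartesianDiffusion:
    """Exact spectral diffusion propagator on the periodic/no-flux rectangle."""

    def __init__(self, domain: SimDomain, Ds: Sequence[float], dt: float):
        n_x, n_y = domain.shape
        kx = 2 * np.pi * np.fft.rfftfreq(n_x, d=domain.Lx / n_x)
        ky = np.pi * np.arange(n_y) / domain.Ly
        k2 = kx[:, None] ** 2 + ky[None, :] ** 2
        self.mults = [np.exp(-D * dt * k2) for D in Ds]

    def step(self, fields):
        out = []
        for f, m in zip(fields, self.mults):
            fh = sfft.rfft(sfft.dct(f, type=2, axis=1), axis=0)
            fh *= m
            out.append(sfft.idct(sfft.irfft(fh, axis=0, n=f.shape[0]),
                                 type=2, axis=1))
        return out


# Compiled kernels for the batched radial sweeps (the integrator's hot
# loop); the numpy fallback below implements the identical arithmetic.
try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _radial_mult_jit(e, a, L_diag, sub, sup, uh, out):
        nb, nr = uh.shape
        for i in range(nb):
            for j in range(nr):
                v = ((1.0 - e[i]) + a[i] * L_diag[i, j]) * uh[i, j]
                if j > 0:
                    v += a[i] * sub[j] * uh[i, j - 1]
                if j < nr - 1:
                    v += a[i] * sup[j] * uh[i, j + 1]
                out[i, j] = v

    @_njit(cache=True)
    def _radial_solve_jit(a, sub, denom, cp, rhs):
        nb, nr = rhs.shape
        for i in range(nb):
            rhs[i, 0] = rhs[i, 0] / denom[i, 0]
            for j in range(1, nr):
                rhs[i, j] = (rhs[i, j] + a[i] * sub[j] * rhs[i, j - 1]) \
                    / denom[i, j]
            for j in range(nr - 2, -1, -1):
                rhs[i, j] = rhs[i, j] - cp[i, j] * rhs[i, j + 1]
except ImportError:           # pragma: no cover - numba is a soft dep
    _radial_mult_jit = None
    _radial_solve_jit = None


class _RadialOp:
    """Batched tridiagonal machinery for the per-mode radial operator.

    For each batch entry (a field or species with its own coefficient
    ``a`` and diagonal shift ``e``) this represents
    A = (1 + e) I - a L_m  and the matching multiply
    (1 - e) I + a L_m, where L_m is the conservative finite-difference
    form of (1/r) d/dr (r d/dr) - m^2/r^2 with zero-flux faces.
    """

    def __init__(self, domain: SimDomain, a_list, shift_list=None):
        n_phi, n_r = domain.shape
        dr = domain.R / n_r
        r = domain.r
        r_minus = np.arange(n_r) * dr          # inner cell faces (0 at axis)
        r_plus = (np.arange(n_r) + 1) * dr     # outer cell faces
        sub = r_minus / (r * dr * dr)          # coef of u_{j-1}; sub[0] = 0
        sup = (r_plus / (r * dr * dr)).copy()
        sup[-1] = 0.0                          # no-flux at r = R
        diag0 = -(sub + sup)
        m = np.arange(n_phi // 2 + 1, dtype=float)
        diag_m = diag0[None, :] - (m[:, None] ** 2) / (r[None, :] ** 2)
        shift_list = shift_list or [0.0] * len(a_list)
        self.n_r, self.n_modes = n_r, m.size
        self.n_batch = len(a_list)
        self.sub, self.sup = sub, sup
        self.a = np.repeat(np.asarray(a_list, dtype=float), self.n_modes)
        self.e = np.repeat(np.asarray(shift_list, dtype=float), self.n_modes)
        diag_all = np.concatenate([diag_m] * self.n_batch, axis=0)
        self.L_diag = diag_all
        A_diag = (1.0 + self.e)[:, None] - self.a[:, None] * diag_all
        # Thomas forward-elimination factors (time-independent)
        self.denom = np.empty_like(A_diag)
        self.cp = np.empty_like(A_diag)
        self.denom[:, 0] = A_diag[:, 0]
        self.cp[:, 0] = (-self.a * sup[0]) / self.denom[:, 0]
        for j in range(1, n_r):
            self.denom[:, j] = A_diag[:, j] \
                - (-self.a * sub[j]) * self.cp[:, j - 1]
            if j < n_r - 1:
                self.cp[:, j] = (-self.a * sup[j]) / self.denom[:, j]

    def mult(self, uh):
        """((1 - e) I + a L) uh, batched tridiagonal multiply."""
        if _radial_mult_jit is not None:
            out = np.empty_like(uh)
            _radial_mult_jit(self.e, self.a, self.L_diag, self.sub,
                             self.sup, uh, out)
            return out
        out = ((1.0 - self.e)[:, None] + self.a[:, None] * self.L_diag) * uh
        out[:, 1:] += (self.a[:, None] * self.sub[1:]) * uh[:, :-1]
        out[:, :-1] += (self.a[:, None] * self.sup[:-1]) * uh[:, 1:]
        return out

    def solve(self, rhs):
        """x with ((1 + e) I - a L) x = rhs (batched Thomas sweeps)."""
        if _radial_solve_jit is not None:
            x = np.ascontiguousarray(rhs)
            _radial_solve_jit(self.a, self.sub, self.denom, self.cp, x)
            return x
        n_r = self.n_r
        dp = np.empty_like(rhs)
        dp[:, 0] = rhs[:, 0] / self.denom[:, 0]
        for j in range(1, n_r):
            dp[:, j] = (rhs[:, j] + (self.a * self.sub[j]) * dp[:, j - 1]) \
                / self.denom[:, j]
        x = np.empty_like(dp)
        x[:, -1] = dp[:, -1]
        for j in range(n_r - 2, -1, -1):
            x[:, j] = dp[:, j] - self.cp[:, j] * x[:, j + 1]
        return x


# TR-BDF2 constants (gamma = 2 - sqrt(2)); both stages share one matrix
_TRBDF2_GAMMA = 2.0 - np.sqrt(2.0)
_TRBDF2_C1 = 1.0 / (_TRBDF2_GAMMA * (2.0 - _TRBDF2_GAMMA))
_TRBDF2_C2 = (1.0 - _TRBDF2_GAMMA) ** 2 / (_TRBDF2_GAMMA
                                           * (2.0 - _TRBDF2_GAMMA))


class _PolarDiffusion:
    """TR-BDF2 radial solves per angular Fourier mode, batched.

    TR-BDF2 is second order and L-stable: the near-origin modes with
    eigenvalues ~ m^2/r^2, which Crank-Nicolson would leave ringing at
    |amplification| ~ 1, are damped outright.  The weighted mean of every
    field is preserved exactly (the m = 0 row sums of L are zero).
    """

    def __init__(self, domain: SimDomain, Ds: Sequence[float], dt: float):
        a = 0.5 * _TRBDF2_GAMMA * dt
        self.op = _RadialOp(domain, [a * D for D in Ds])
        self.n_fields = len(Ds)

    def step(self, fields):
        op = self.op
        uh = np.concatenate([sfft.rfft(f, axis=0) for f in fields], axis=0)
        ustar = op.solve(op.mult(uh))                    # trapezoidal stage
        unew = op.solve(_TRBDF2_C1 * ustar - _TRBDF2_C2 * uh)  # BDF2 stage
        n_phi = fields[0].shape[0]
        nm = op.n_modes
        return [sfft.irfft(unew[i * nm:(i + 1) * nm], axis=0, n=n_phi)
                for i in range(self.n_fields)]


def _make_diffusion(domain: SimDomain, Ds, dt):
    if domain.is_polar:
        return _PolarDiffusion(domain, Ds, dt)
    return _CartesianDiffusion(domain, Ds, dt)


class _LinearSpeciesStepper:
    """Crank-Nicolson step of dX/dt = k - delta*X + D lap X (one species).

    The linear dynamics are advanced as one unsplit CN step, so the
    stepper's fixed point is exactly the discrete steady state
    (delta - D L) X = k.  Modulator fields are smooth, so CN's weak
    damping of near-origin stiff modes is immaterial here.
    """

    def __init__(self, domain: SimDomain, D: float, delta: float,
                 k: np.ndarray, dt: float):
        k = np.broadcast_to(np.asarray(k, dtype=float), domain.shape)
        if domain.is_polar:
            self._op = _RadialOp(domain, [0.5 * dt * D],
                                 [0.5 * dt * delta])
            self._k_term = sfft.rfft(dt * k, axis=0)
            self._cart = None
        else:
            self._op = None
            n_x, n_y = domain.shape
            kx = 2 * np.pi * np.fft.rfftfreq(n_x, d=domain.Lx / n_x)
            ky = np.pi * np.arange(n_y) / domain.Ly
            lam = -D * (kx[:, None] ** 2 + ky[None, :] ** 2) - delta
            self._A = 1.0 - 0.5 * dt * lam
            self._B = 1.0 + 0.5 * dt * lam
            self._k_hat = sfft.rfft(sfft.dct(dt * k, type=2, axis=1), axis=0)

    def step(self, X: np.ndarray) -> np.ndarray:
        if self._op is not None:
            xh = sfft.rfft(X, axis=0)
            xh = self._op.solve(self._op.mult(xh) + self._k_term)
            return sfft.irfft(xh, axis=0, n=X.shape[0])
        xh = sfft.rfft(sfft.dct(X, type=2, axis=1), axis=0)
        xh = (self._B * xh + self._k_hat) / self._A
        return sfft.idct(sfft.irfft(xh, axis=0, n=X.shape[0]),
                         type=2, axis=1)


# --------------------------------------------------------------------------
# modulator species (fully coupled model)
# --------------------------------------------------------------------------

@dataclass
class Modulator:
    """A diffusing species X with dX/dt = k(r) - delta*X + D lap X."""

    name: str
    k: np.ndarray | float       # source (activation) field
    delta: float                # first-order decay, 1/s
    D: float                    # diffusivity, um^2/s
    X0: np.ndarray | float = 0.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("modulator decay rate must be positive")
        if self.D < 0:
            raise ValueError("modulator diffusivity must be non-negative")


@dataclass
class Coupling:
    """rate <- intercept + slope * X, evaluated pointwise each step."""

    modulator: str
    rate: str
    intercept: float = 0.0
    slope: float = 1.0


@dataclass
class ModulatorSystem:
    modulators: list
    couplings: list


def attach_modulators(modulators: Sequence[Modulator],
                      couplings: Sequence[Coupling]) -> ModulatorSystem:
    """Validate and bundle modulators + couplings for ``integrate``."""
    names = {m.name for m in modulators}
    for cp in couplings:
        if cp.modulator not in names:
            raise ValueError(f"coupling references unknown modulator "
                             f"{cp.modulator!r}")
        if cp.rate not in RATE_NAMES:
            raise ValueError(f"coupling references unknown rate {cp.rate!r}")
    return ModulatorSystem(list(modulators), list(couplings))


# --------------------------------------------------------------------------
# trajectory container
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    times: np.ndarray
    states: list                       # list[FieldState]
    domain: SimDomain
    metadata: dict = dfield(default_factory=dict)
    modulator_states: dict = dfield(default_factory=dict)  # name -> [arrays]

    @property
    def final(self) -> FieldState:
        return self.states[-1]

    def conservation_drift(self) -> float:
        """Max relative drift of either pool total across snapshots."""
        dom = self.domain
        tot_u = np.array([dom.mean(s.u + s.v) for s in self.states])
        tot_G = np.array([dom.mean(s.G + s.g) for s in self.states])
        drift_u = np.abs(tot_u - tot_u[0]).max() / abs(tot_u[0])
        if abs(tot_G[0]) > 0:
            drift_G = np.abs(tot_G - tot_G[0]).max() / abs(tot_G[0])
        else:
            drift_G = np.abs(tot_G).max()
        return float(max(drift_u, drift_G))


# --------------------------------------------------------------------------
# reaction substeps
# --------------------------------------------------------------------------

def _reaction_substep(u, v, G, g, rates, n, dt, fast):
    """Advance the pointwise kinetics by dt holding u+v and G+g fixed.

    Overflow in diverging (to-be-rejected) candidate runs is tolerated:
    non-finite values are detected by the integrator's blow-up check.
    """
    s = u + v
    sg = G + g

    def f(uu, GG):
        vv = s - uu
        du = rates["b"] * vv + rates["gamma"] * vv * hill(uu, rates["K"], n) \
            - rates["sigma"] * uu - rates["e"] * GG * uu
        dG = rates["c"] * uu * (sg - GG) - rates["d"] * GG
        return du, dG

    if fast:  # RK2 midpoint
        du1, dG1 = f(u, G)
        du2, dG2 = f(u + 0.5 * dt * du1, G + 0.5 * dt * dG1)
        un = u + dt * du2
        Gn = G + dt * dG2
    else:     # classic RK4
        du1, dG1 = f(u, G)
        du2, dG2 = f(u + 0.5 * dt * du1, G + 0.5 * dt * dG1)
        du3, dG3 = f(u + 0.5 * dt * du2, G + 0.5 * dt * dG2)
        du4, dG4 = f(u + dt * du3, G + dt * dG3)
        un = u + (dt / 6) * (du1 + 2 * du2 + 2 * du3 + du4)
        Gn = G + (dt / 6) * (dG1 + 2 * dG2 + 2 * dG3 + dG4)
    return un, s - un, Gn, sg - Gn


# --------------------------------------------------------------------------
# main integrator
# --------------------------------------------------------------------------

def integrate(state0: FieldState, params: WPGAPParams, domain: SimDomain,
              *, dt: float = 0.025, t_final: float = 40.0,
              snapshot_every: float = 1.0,
              profiles: Mapping[str, np.ndarray] | None = None,
              modulator_system: ModulatorSystem | None = None,
              fast: bool = False, seed: int | None = None) -> Trajectory:
    """Advance u, v, G, g (and any modulators) to ``t_final``.

    ``profiles`` maps rate names to grid arrays (spatially modulated rates).
    ``fast`` switches the reaction substep from RK4 to RK2, the documented
    low-cost mode used during parameter searches.  ``seed`` is bookkeeping
    only (recorded in metadata); randomness lives in the initial condition.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state0.check_shapes()
    if np.min(state0.u) < -1e-8 or np.min(state0.v) < -1e-8:
        raise ValueError("initial fields must be non-negative")

    n_steps = int(round(t_final / dt))
    snap_stride = max(1, int(round(snapshot_every / dt)))
    rates0 = _resolve_rates(params, profiles)
    for name, val in rates0.items():
        if isinstance(val, np.ndarray) and val.shape != domain.shape:
            raise ValueError(f"profile {name!r} does not match the grid")

    Ds = [params.Du, params.Dv, params.DG, params.Dg]
    mods = modulator_system.modulators if modulator_system else []
    coups = modulator_system.couplings if modulator_system else []
    mod_idx = {m.name: i for i, m in enumerate(mods)}
    diff_half = _make_diffusion(domain, Ds, dt / 2)
    diff_full = _make_diffusion(domain, Ds, dt)
    mod_steppers = [_LinearSpeciesStepper(domain, m.D, m.delta, m.k, dt)
                    for m in mods]

    fields = [state0.u.astype(float).copy(), state0.v.astype(float).copy(),
              state0.G.astype(float).copy(), state0.g.astype(float).copy()]
    Xs = [np.broadcast_to(np.asarray(m.X0, dtype=float),
                          domain.shape).copy() for m in mods]

    rates = dict(rates0)

    def apply_couplings():
        for cp in coups:
            rates[cp.rate] = cp.intercept + cp.slope * Xs[mod_idx[cp.modulator]]

    apply_couplings()

    times = [0.0]
    states = [FieldState(*[f.copy() for f in fields], t=0.0, domain=domain)]
    mod_snaps = {m.name: [Xs[i].copy()] for i, m in enumerate(mods)}

    pending_half = True  # a leading half diffusion step is owed
    for k in range(1, n_steps + 1):
        with np.errstate(over="ignore", invalid="ignore",
                         divide="ignore"):
            if pending_half:
                fields = diff_half.step(fields)
                pending_half = False
            apply_couplings()
            fields = list(_reaction_substep(*fields, rates, params.n, dt,
                                            fast))
            for i, stepper in enumerate(mod_steppers):
                Xs[i] = stepper.step(Xs[i])
        t = k * dt
        if k % 100 == 0 and not np.isfinite(fields[0]).all():
            raise BlowUpError(t)
        at_snap = (k % snap_stride == 0) or (k == n_steps)
        with np.errstate(over="ignore", invalid="ignore",
                         divide="ignore"):
            if at_snap:
                fields = diff_half.step(fields)
                pending_half = True
            else:
                fields = diff_full.step(fields)
        if at_snap:
            if not (np.all(np.isfinite(fields[0]))
                    and np.all(np.isfinite(fields[2]))):
                raise BlowUpError(t)
            times.append(t)
            states.append(FieldState(*[f.copy() for f in fields],
                                     t=t, domain=domain))
            for i, m in enumerate(mods):
                mod_snaps[m.name].append(Xs[i].copy())

    meta = {"dt": dt, "t_final": t_final, "fast": fast, "seed": seed,
            "params": params.to_dict(), "geometry": domain.geometry,
            "grid": list(domain.shape)}
    return Trajectory(np.asarray(times), states, domain, meta, mod_snaps)
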