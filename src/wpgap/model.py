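"""WPGAP reaction terms, homogeneous steady states and mass bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .domain import SimDomain
from .params import WPGAPParams, RATE_NAMES

__all__ = ["FieldState", "reaction_rhs", "homogeneous_steady_state",
           "total_mass", "hill"]


@dataclass
class FieldState:
    """The four concentration fields at one time point."""

    u: np.ndarray
    v: np.ndarray
    G: np.ndarray
    g: np.ndarray
    t: float = 0.0
    domain: SimDomain | None = field(default=None, repr=False)

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.v.copy(), self.G.copy(),
                          self.g.copy(), self.t, self.domain)

    def check_shapes(self) -> None:
        if not (self.u.shape == self.v.shape == self.G.shape == self.g.shape):
            raise ValueError("field shapes differ")
        if self.domain is not None and self.u.shape != self.domain.shape:
            raise ValueError("field shape does not match domain grid")


def hill(u, K, n):
    """Hill response u^n / (K^n + u^n), with u clipped at 0.

    Clipping guards against negative-base powers from tiny solver
    undershoots; it does not alter the dynamics in the physical regime.
    """
    uc = np.maximum(u, 0.0)
    un = uc ** n
    return un / (K ** n + un)


def _resolve_rates(params: WPGAPParams,
                   profiles: Mapping[str, np.ndarray] | None):
    """Return the seven kinetic rates, each a scalar or a grid array."""
    rates = {name: getattr(params, name) for name in RATE_NAMES}
    if profiles:
        unknown = set(profiles) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"profiles for unknown rates: {sorted(unknown)}")
        rates.update(profiles)
    return rates


def reaction_rhs(state: FieldState, params: WPGAPParams,
                 profiles: Mapping[str, np.ndarray] | None = None):
    """Pointwise reaction time-derivatives (du, dv, dG, dg), no diffusion.

    Any rate present in ``profiles`` is evaluated with its local value, which
    is how IgG-disk-shaped spatial modulation enters the model.  dv = -du and
    dg = -dG exactly, so pool totals are conserved by construction.
    """
    state.check_shapes()
    u, v, G, g = state.u, state.v, state.G, state.g
    rt = _resolve_rates(params, profiles)
    for name, val in rt.items():
        if isinstance(val, np.ndarray) and val.shape != u.shape:
            raise ValueError(f"profile {name!r} shape {val.shape} does not "
                             f"match field shape {u.shape}")
    du = rt["b"] * v + rt["gamma"] * v * hill(u, rt["K"], params.n) \
        - rt["sigma"] * u - rt["e"] * G * u
    dG = rt["c"] * u * g - rt["d"] * G
    return du, -du, dG, -dG


def homogeneous_steady_state(params: WPGAPParams, t_end: float = 1000.0,
                             u0: float = 0.0, G0: float = 0.0):
    """Steady state of the well-mixed (diffusion-free) system.

    Integrates the reduced ODEs for (u, G) with v = T - u and g = Tg - G to
    ``t_end`` (default 1000 s), so both conservation sums hold exactly.
    Default initial condition is fully inactive pools; with multistable
    kinetics the result can depend on (u0, G0).
    """

    def rhs(_t, yy):
        u, G = yy
        v = params.T - u
        g = params.Tg - G
        du = params.b * v + params.gamma * v * hill(u, params.K, params.n) \
            - params.sigma * u - params.e * G * u
        dG = params.c * u * g - params.d * G
        return (du, dG)

    sol = solve_ivp(rhs, (0.0, t_end), (u0, G0), method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"steady-state integration failed: {sol.message}")
    u_ss, G_ss = sol.y[:, -1]
    return float(u_ss), float(params.T - u_ss), float(G_ss), \
        float(params.Tg - G_ss)


def total_mass(state: FieldState, domain: SimDomain | None = None):
    """Domain means of u+v and G+g (the conserved pool totals).

    Concentrations are surface densities, so the conserved "mass" is the
    area-weighted mean: for a closed run it equals (T, Tg) at all times.
    """
    dom = domain or state.domain
    if dom is None:
        raise ValueError("a domain with quadrature weights is required")
    return dom.mean(state.u + state.v), dom.mean(state.G + state.g)
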