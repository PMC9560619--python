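"""Spatial rate profiles: Gaussian rings, the gradient sub-model, and
logistic radial profiles.

Three ways a kinetic rate can acquire spatial structure around an IgG disk:

1. Two-step mechanism: a pre-formed ring-shaped modulator M(r) shifts a
   rate as omega(r) = omega1 +/- omega2 * M(r).
2. Gradient mechanism: an upstream species X is activated over the disk
   (step source), decays everywhere and diffuses; its steady profile is
   well approximated by a logistic function of r, which is then used as
   the profile of the positive-feedback rate gamma and GAP activation
   rate c.
3. Fully coupled: the X-species is simulated alongside the GTPase fields
   (see :mod:`wpgap.solver` modulators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .domain import SimDomain

__all__ = ["RingModulator", "ModulatorModel", "LogisticParams",
           "LogisticFit", "gaussian_ring", "modulated_rate",
           "step_activation", "simulate_gradient", "fit_logistic",
           "logistic", "spatial_rate_profiles",
           "representative_gradient_profiles", "REPRESENTATIVE"]


# --------------------------------------------------------------------------
# Gaussian-ring modulator (two-step mechanism)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RingModulator:
    """Ring-shaped modulator concentration M(r), peak at ``center``."""

    center: float = 2.0       # ring radius, um
    variance: float = 0.04    # um^2 (ring half-width ~0.2 um)
    amplitude: float = 1.0
    orientation: str = "normal"   # "normal" | "inverted"

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.orientation not in ("normal", "inverted"):
            raise ValueError("orientation must be 'normal' or 'inverted'")


def gaussian_ring(domain: SimDomain, mod: RingModulator) -> np.ndarray:
    """Tabulate M(r) on the grid.

    ``inverted`` returns amplitude*(1 - exp(...)): high everywhere except
    a trough on the ring, used to couple rates that must *drop* on the ring.
    """
    r = domain.radius_grid()
    bump = np.exp(-((r - mod.center) ** 2) / (2.0 * mod.variance))
    if mod.orientation == "inverted":
        return mod.amplitude * (1.0 - bump)
    return mod.amplitude * bump


def modulated_rate(omega1: float, omega2: float, sign: str,
                   M: np.ndarray) -> np.ndarray:
    """omega(r) = omega1 +/- omega2 * M(r), validated non-negative."""
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    out = omega1 + omega2 * M if sign == "+" else omega1 - omega2 * M
    if np.min(out) < 0:
        raise ValueError("modulated rate is negative somewhere on the grid")
    return out


# --------------------------------------------------------------------------
# gradient sub-model: dX/dt = k(r) - delta*X + D (1/r) d/dr (r dX/dr)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulatorModel:
    """Gradient sub-model of a species activated over the IgG disk."""

    k_disk: float             # activation over the disk
    k_basal: float            # activation elsewhere
    mu_F: float               # disk radius, um
    delta_x: float            # decay rate, 1/s
    D_x: float                # diffusivity, um^2/s

    def __post_init__(self):
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")
        if self.D_x < 0:
            raise ValueError("D_x must be non-negative")
        if self.k_disk < 0 or self.k_basal < 0:
            raise ValueError("activation rates must be non-negative")


def step_activation(r: np.ndarray, mod: ModulatorModel) -> np.ndarray:
    """Step source k(r): k_disk for r < mu_F, k_basal beyond."""
    return np.where(r < mod.mu_F, mod.k_disk, mod.k_basal)


def _radial_laplacian_tridiag(r: np.ndarray, dr: float):
    """Conservative FD diagonals of (1/r) d/dr (r d/dr), no-flux ends."""
    n = r.size
    r_minus = np.arange(n) * dr
    r_plus = (np.arange(n) + 1) * dr
    sub = r_minus / (r * dr * dr)
    sup = r_plus / (r * dr * dr)
    sup = sup.copy()
    sup[-1] = 0.0
    diag = -(sub + sup)
    return sub, diag, sup


def simulate_gradient(mod: ModulatorModel, domain: SimDomain,
                      t_final: float | None = None) -> np.ndarray:
    """Radial profile X(r) on ``domain.r``.

    With ``t_final=None`` (default) the steady state is computed by a
    direct linear solve of (delta - D L) X = k(r); otherwise the radially
    symmetric PDE is integrated to ``t_final`` from X=0.
    """
    if not domain.is_polar:
        raise ValueError("gradient sub-model is defined on the disk domain")
    r = domain.r
    dr = float(r[1] - r[0])
    k = step_activation(r, mod)
    sub, diag, sup = _radial_laplacian_tridiag(r, dr)
    n = r.size

    if t_final is None:
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        L = sp.diags([sub[1:], diag, sup[:-1]], offsets=(-1, 0, 1),
                     format="csc")
        A = sp.eye(n, format="csc") * mod.delta_x - mod.D_x * L
        X = spla.spsolve(A, k)
    else:
        def rhs(_t, X):
            lap = diag * X
            lap[1:] += sub[1:] * X[:-1]
            lap[:-1] += sup[:-1] * X[1:]
            return k - mod.delta_x * X + mod.D_x * lap

        sol = solve_ivp(rhs, (0.0, t_final), np.zeros(n), method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"gradient integration failed: {sol.message}")
        X = sol.y[:, -1]
    if not np.all(np.isfinite(X)):
        raise RuntimeError("gradient solution diverged")
    return X


# --------------------------------------------------------------------------
# logistic profile and its fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticParams:
    """f(r) = beta + alpha / (1 + exp(km (r - r0))).

    ``beta`` is the far-field (minimum) level for km > 0, ``alpha`` the
    amplitude, so the maximum is alpha + beta; km < 0 inverts the profile
    (hole geometry).
    """

    beta: float
    alpha: float
    km: float
    r0: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha (amplitude) must be non-negative; "
                             "max level below min level")

    @classmethod
    def from_min_max(cls, minimum: float, maximum: float, km: float,
                     r0: float) -> "LogisticParams":
        return cls(beta=minimum, alpha=maximum - minimum, km=km, r0=r0)

    @property
    def maximum(self) -> float:
        return self.beta + self.alpha

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return logistic(r, self.beta, self.alpha, self.km, self.r0)


def logistic(r, beta, alpha, km, r0):
    return beta + alpha / (1.0 + np.exp(np.clip(km * (r - r0), -500, 500)))


@dataclass(frozen=True)
class LogisticFit:
    params: LogisticParams
    rms: float                 # root-mean-square residual
    identifiable: bool         # False when the profile is ~constant


def fit_logistic(r: np.ndarray, profile: np.ndarray) -> LogisticFit:
    """Constrained least-squares logistic fit (SLSQP).

    A near-constant profile yields alpha ~ 0 with km, r0 unidentifiable
    (flagged, not an error).
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(profile, dtype=float)
    if r.size < 8:
        raise ValueError("need at least 8 radial samples")
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-300)
    if span < 1e-10 * scale:
        params = LogisticParams(beta=float(y.mean()), alpha=0.0, km=1.0,
                                r0=float(r.mean()))
        return LogisticFit(params, rms=float(y.std()), identifiable=False)

    decreasing = y[0] > y[-1]
    km0 = 2.0 if decreasing else -2.0
    # midpoint guess: radius nearest the half-height crossing
    half = y.min() + span / 2
    r0_guess = float(r[np.argmin(np.abs(y - half))])
    x0 = np.array([y.min(), span, km0, r0_guess])

    def sse(p):
        return float(np.sum((logistic(r, *p) - y) ** 2))

    res = minimize(sse, x0, method="SLSQP",
                   bounds=[(None, None), (0.0, None), (None, None),
                           (0.0, None)],
                   options={"maxiter": 500, "ftol": 1e-14})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"logistic fit failed: {res.message}")
    params = LogisticParams(*[float(v) for v in res.x])
    rms = float(np.sqrt(res.fun / r.size))
    return LogisticFit(params, rms=rms, identifiable=True)


# --------------------------------------------------------------------------
# gamma(r) / c(r) parameterization of the gradient mechanism
# --------------------------------------------------------------------------

def spatial_rate_profiles(gamma_params: LogisticParams,
                          c_params: LogisticParams,
                          domain: SimDomain):
    """Grid profiles (gamma(r), c(r), gamma/c ratio) for the WPGAP model."""
    r = domain.radius_grid()
    gam = gamma_params(r)
    cc = c_params(r)
    with np.errstate(divide="ignore"):
        ratio = gam / cc
    return gam, cc, ratio


#: representative spatially-modulated parameter values (posterior means of
#: the search; minima and b, sigma were fixed during the search)
REPRESENTATIVE = {
    "gamma_max": 9.6, "gamma_km": 2.04, "gamma_alpha": 5e-3,
    "c_max": 0.08, "c_km": 13.0, "c_alpha": 5e-3,
    "b": 2e-3, "sigma": 0.4, "d": 43.0, "e": 31.3,
}


def representative_gradient_profiles(r0: float = 2.0, hole: bool = False):
    """Representative logistic parameters for gamma(r) and c(r).

    ``r0`` is the disk (or hole) radius: the logistic midpoint sits at the
    IgG edge.  ``hole=True`` negates both decay rates, inverting the
    profiles (IgG everywhere except a central hole).
    """
    sgn = -1.0 if hole else 1.0
    gp = LogisticParams.from_min_max(REPRESENTATIVE["gamma_alpha"],
                                     REPRESENTATIVE["gamma_max"],
                                     sgn * REPRESENTATIVE["gamma_km"], r0)
    cp = LogisticParams.from_min_max(REPRESENTATIVE["c_alpha"],
                                     REPRESENTATIVE["c_max"],
                                     sgn * REPRESENTATIVE["c_km"], r0)
    return gp, cp
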