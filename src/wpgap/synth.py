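"""Synthetic inputs: noisy initial conditions, rosette seeds, score targets.

Initialization protocol: every field starts at the homogeneous steady state
of the well-mixed kinetics (computed with the *basal* values of any
spatially varying rate), then activation noise is injected by converting a
per-pixel amount delta ~ U(0, f * v_ss) of inactive GTPase to active.
Unseeded runs use f = 0.2; seeded runs use f = 0.1 plus a rosette-shaped
seed normalized to peak 1 and scaled by 0.1 * v_ss, also converted from v
to u.  Conversion (rather than addition) keeps the pool totals exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .domain import SimDomain
from .model import FieldState, homogeneous_steady_state
from .params import WPGAPParams
from .scoring import ScoreTarget, radial_profile

__all__ = ["InitSpec", "RosetteTemplate", "noisy_initial_condition",
           "rosette_seed", "make_score_target", "DEFAULT_TEMPLATE"]


@dataclass(frozen=True)
class RosetteTemplate:
    """Ring of equally spaced Gaussian bumps used as seed or analytic target.

    Spot width default 0.3 um: comparable to the emergent spots, so a seed
    at the printed 0.1*v_ss amplitude survives diffusion long enough to
    ignite the positive feedback.
    """

    n_spots: int = 8
    ring_radius: float = 2.2      # um; spots sit just outside the IgG edge
    spot_sigma: float = 0.3       # um
    amplitude: float = 1.0
    phase: float = 0.0            # angular offset, rad

    def __post_init__(self):
        if self.n_spots < 1:
            raise ValueError("need at least one spot")
        if self.spot_sigma <= 0 or self.ring_radius < 0:
            raise ValueError("invalid template geometry")

    def field(self, domain: SimDomain) -> np.ndarray:
        """Sum of Gaussian bumps on the grid, peak-normalized to amplitude."""
        r = domain.radius_grid()
        phi = domain.angle_grid()
        x, y = r * np.cos(phi), r * np.sin(phi)
        out = np.zeros(domain.shape)
        for k in range(self.n_spots):
            a = self.phase + 2 * np.pi * k / self.n_spots
            cx, cy = self.ring_radius * np.cos(a), self.ring_radius * np.sin(a)
            out += np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                          / (2 * self.spot_sigma ** 2))
        peak = out.max()
        if peak > 0:
            out *= self.amplitude / peak
        return out


DEFAULT_TEMPLATE = RosetteTemplate()


@dataclass(frozen=True)
class InitSpec:
    """Initialization protocol for a simulation."""

    rng_seed: int = 0
    seed_pattern: str = "none"            # "none" | "rosette"
    noise_fraction_max: float | None = None  # default 0.2 / 0.1 (seeded)
    seed_amplitude_fraction: float = 0.1
    noise_gap: bool = False               # also jitter the GAP pools
    template: RosetteTemplate = DEFAULT_TEMPLATE

    def __post_init__(self):
        if self.seed_pattern not in ("none", "rosette"):
            raise ValueError("seed_pattern must be 'none' or 'rosette'")
        f = self.noise_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("noise fraction must be in [0, 1]")
        if not 0.0 <= self.seed_amplitude_fraction <= 1.0:
            raise ValueError("seed amplitude fraction must be in [0, 1]")

    @property
    def noise_fraction(self) -> float:
        if self.noise_fraction_max is not None:
            return self.noise_fraction_max
        return 0.1 if self.seed_pattern == "rosette" else 0.2

    # -- YAML config -----------------------------------------------------
    def to_yaml(self) -> str:
        import dataclasses

        import yaml
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "InitSpec":
        import yaml
        payload = yaml.safe_load(text)
        tpl = payload.pop("template", None)
        template = RosetteTemplate(**tpl) if tpl else DEFAULT_TEMPLATE
        return cls(template=template, **payload)


def rosette_seed(template: RosetteTemplate, v_ss: float,
                 domain: SimDomain) -> np.ndarray:
    """Additive u-field: normalized rosette scaled by the seed fraction of v_ss.

    The caller debits the same amount from v (see noisy_initial_condition).
    """
    if template.ring_radius >= (domain.R or np.inf):
        raise ValueError("seed ring lies outside the domain")
    out = template.field(domain)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out * 0.1 * v_ss


def noisy_initial_condition(params: WPGAPParams, domain: SimDomain,
                            spec: InitSpec) -> FieldState:
    """Steady state + activation noise (+ optional rosette seed).

    For runs with spatially varying rates, pass ``params`` holding the
    basal (far-field) values of those rates — the steady state is
    deliberately the one far from the IgG disk.
    """
    u_ss, v_ss, G_ss, g_ss = homogeneous_steady_state(params)
    rng = np.random.default_rng(spec.rng_seed)
    delta = rng.uniform(0.0, spec.noise_fraction * v_ss, domain.shape)
    u = np.full(domain.shape, u_ss) + delta
    v = np.full(domain.shape, v_ss) - delta
    if spec.seed_pattern == "rosette":
        seed_field = rosette_seed(
            spec.template, v_ss, domain) \
            * (spec.seed_amplitude_fraction / 0.1)
        u += seed_field
        v -= seed_field
    if np.min(v) < 0:
        raise ValueError("initialization would drive v negative; "
                         "reduce noise/seed fractions")
    G = np.full(domain.shape, G_ss)
    g = np.full(domain.shape, g_ss)
    if spec.noise_gap and params.Tg > 0:
        dg = rng.uniform(0.0, spec.noise_fraction * g_ss, domain.shape)
        G = G + dg
        g = g - dg
        if np.min(g) < 0:
            raise ValueError("GAP noise would drive g negative")
    return FieldState(u, v, G, g, t=0.0, domain=domain)


def make_score_target(mode: str, *, field: np.ndarray | None = None,
                      domain: SimDomain, template: RosetteTemplate | None = None,
                      amplitude: float = 1.0, n_bins: int = 32) -> ScoreTarget:
    """Build the reference rosette profiles for the score function.

    ``mode='two-step'``: ``field`` is the final active-GTPase field of a
    two-step (ring-modulated) simulation — the canonical choice.
    ``mode='analytic'``: a synthetic stand-in built from ``template``,
    used when no two-step simulation is at hand.
    """
    if mode == "two-step":
        if field is None:
            raise ValueError("two-step mode requires a simulated field")
    elif mode == "analytic":
        tpl = template or DEFAULT_TEMPLATE
        field = amplitude * tpl.field(domain)
    else:
        raise ValueError("mode must be 'two-step' or 'analytic'")

    R = domain.R if domain.is_polar else min(domain.Lx, domain.Ly) / 2
    edges = np.linspace(0.0, R, n_bins + 1)
    mean = radial_profile(field, domain, edges)
    mean_sq = radial_profile(field ** 2, domain, edges)
    std_full = np.sqrt(np.maximum(mean_sq - mean ** 2, 0.0))
    if std_full.max() <= 1e-12 * max(np.abs(mean).max(), 1.0):
        warnings.warn("target field has no radial-std peak; "
                      "it does not look like a rosette", stacklevel=2)
    return ScoreTarget(edges, mean, std_full)
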