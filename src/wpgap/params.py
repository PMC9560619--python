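"""Parameter container for the wave-pinning GTPase + GAP (WPGAP) circuit.

The model tracks four surface densities on the ventral membrane: active
GTPase ``u``, inactive GTPase ``v``, active GAP ``G`` and inactive GAP
``g`` (all molecules/um^2).  Kinetics are

    du/dt = b*v + gamma*v*u^n/(K^n + u^n) - sigma*u - e*G*u
    dv/dt = -du/dt
    dG/dt = c*u*g - d*G
    dg/dt = -dG/dt

so the pool totals T = <u + v> and Tg = <G + g> are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Mapping

import yaml

__all__ = ["WPGAPParams", "baseline_params", "RATE_NAMES"]

#: kinetic rates that may be replaced by a spatial profile
RATE_NAMES = ("b", "gamma", "K", "sigma", "c", "d", "e")


@dataclass(frozen=True)
class WPGAPParams:
    """Kinetic rates, diffusivities and pool totals of the WPGAP circuit.

    Units: first-order rates in 1/s, bimolecular rates (``c``, ``e``) in
    um^2/s, diffusivities in um^2/s, concentrations in molecules/um^2.
    """

    b: float = 1.0          # basal GTPase activation, 1/s
    gamma: float = 20.0     # max self-positive feedback rate, 1/s
    K: float = 200.0        # half-maximal active-GTPase concentration
    n: float = 2.0          # Hill coefficient
    sigma: float = 10.0     # basal GTPase inactivation, 1/s
    c: float = 0.05         # GAP activation, um^2/s
    d: float = 10.0         # GAP inactivation, 1/s
    e: float = 10.0         # GAP-mediated GTPase inactivation, um^2/s
    Du: float = 0.04        # active (membrane-bound) GTPase diffusion
    Dv: float = 4.0         # inactive (cytosolic) GTPase diffusion
    DG: float = 4.0         # active GAP diffusion
    Dg: float = 4.0         # inactive GAP diffusion
    T: float = 808.0        # total GTPase, molecules/um^2
    Tg: float = 10.0        # total GAP, molecules/um^2

    def __post_init__(self) -> None:
        for name in ("b", "gamma", "sigma", "c", "d", "e",
                     "Du", "Dv", "DG", "Dg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.Tg < 0:
            raise ValueError("Tg must be non-negative")

    @property
    def polarizable(self) -> bool:
        """Whether the cytosolic species is fast enough for wave pinning."""
        return self.Du == 0 or self.Dv / self.Du >= 10.0

    def replace(self, **kwargs) -> "WPGAPParams":
        return replace(self, **kwargs)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "WPGAPParams":
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "WPGAPParams":
        return cls.from_dict(yaml.safe_load(text))


def baseline_params() -> WPGAPParams:
    """Spot-forming baseline parameter set (all defaults).

    Calibrated so that with Du = 0.04 um^2/s (the single-particle-tracking
    estimate for membrane-bound Cdc42) spots have effective radius ~0.31 um.
    """
    return WPGAPParams()
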