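"""Simulation domains: a polar disk and a periodic rectangle.

Disk (default R = 4 um): periodic in the angle phi, no-flux (Neumann) at
r = R.  The radial grid is cell-centered, r_j = (j + 1/2) dr, which keeps
the conservative finite-difference Laplacian regular at the origin without
placing a node at r = 0.

Rectangle: periodic in x, no-flux in y (cell-centered in y so the Neumann
condition is the natural one for a cosine expansion).

Field arrays live on the grid with shape ``(n_angular, n_radial)`` for the
disk and ``(n_x, n_y)`` for the rectangle.  ``weights`` are midpoint
quadrature weights (including the r Jacobian on the disk); they sum to the
domain area exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimDomain", "build_disk", "build_rectangle", "build_domain"]


@dataclass(frozen=True)
class SimDomain:
    geometry: str               # "polar-disk" | "cartesian"
    shape: tuple                # (n_phi, n_r) or (n_x, n_y)
    R: float | None = None      # disk radius, um
    Lx: float | None = None
    Ly: float | None = None
    # coordinate arrays (1D)
    phi: np.ndarray | None = field(default=None, repr=False)
    r: np.ndarray | None = field(default=None, repr=False)
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)  # 2D quadrature

    @property
    def area(self) -> float:
        return float(self.weights.sum())

    @property
    def is_polar(self) -> bool:
        return self.geometry == "polar-disk"

    def mean(self, f: np.ndarray) -> float:
        """Area-weighted spatial mean of a field."""
        return float((self.weights * f).sum() / self.area)

    def integral(self, f: np.ndarray) -> float:
        return float((self.weights * f).sum())

    def radius_grid(self) -> np.ndarray:
        """2D array of radial coordinate (distance from disk center)."""
        if self.is_polar:
            return np.broadcast_to(self.r, self.shape).copy()
        xc, yc = self.Lx / 2, self.Ly / 2
        return np.hypot(self.x[:, None] - xc, self.y[None, :] - yc)

    def angle_grid(self) -> np.ndarray:
        if self.is_polar:
            return np.broadcast_to(self.phi[:, None], self.shape).copy()
        xc, yc = self.Lx / 2, self.Ly / 2
        return np.mod(
            np.arctan2(self.y[None, :] - yc, self.x[:, None] - xc), 2 * np.pi
        )


def build_disk(R: float = 4.0, n_phi: int = 256, n_r: int = 128) -> SimDomain:
    """Polar disk domain, periodic in phi, no-flux at r = R."""
    if R <= 0 or n_phi <= 0 or n_r <= 0:
        raise ValueError("radius and grid dimensions must be positive")
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    dr = R / n_r
    r = (np.arange(n_r) + 0.5) * dr
    dphi = 2 * np.pi / n_phi
    w = np.broadcast_to(r * dr * dphi, (n_phi, n_r)).copy()
    return SimDomain(geometry="polar-disk", shape=(n_phi, n_r), R=R,
                     phi=phi, r=r, weights=w)


def build_rectangle(Lx: float = 5.0, Ly: float = 5.0,
                    n_x: int = 128, n_y: int = 128) -> SimDomain:
    """Rectangle, periodic in x, no-flux in y."""
    if Lx <= 0 or Ly <= 0 or n_x <= 0 or n_y <= 0:
        raise ValueError("extents and grid dimensions must be positive")
    x = np.arange(n_x) * (Lx / n_x)
    y = (np.arange(n_y) + 0.5) * (Ly / n_y)
    w = np.full((n_x, n_y), (Lx / n_x) * (Ly / n_y))
    return SimDomain(geometry="cartesian", shape=(n_x, n_y),
                     Lx=Lx, Ly=Ly, x=x, y=y, weights=w)


def build_domain(geometry: str, **kwargs) -> SimDomain:
    if geometry == "polar-disk":
        return build_disk(**kwargs)
    if geometry == "cartesian":
        return build_rectangle(**kwargs)
    raise ValueError(f"unknown geometry {geometry!r}")
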