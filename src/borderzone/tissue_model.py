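"""Heterogeneous cell network: grid, border-zone profiles, coupling.

The tissue is a rectangular grid of cells joined to nearest neighbours by
Ohmic contacts (four in 2D, six in 3D).  Macroscopic recovery from
ischaemia is imposed as moving profiles of voltage diffusivity D(y, t) and
excitability alpha(y, t): each is a clamped monotone ramp between the
moving limits y1(t) = y1_0 + u t and y2(t) = y2_0 + u t, flat below and
above.  Microscopic heterogeneity adds a frozen i.i.d. Gaussian deviate,
scaled by the intensity nu, to each cell's alpha.

Array layout: fields are indexed ``[iy, ix]`` in 2D and ``[iy, ix, iz]``
in 3D; the border gradient always runs along axis 0 (the y axis) and the
advection direction used elsewhere is axis 1 (x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GridSpec",
    "BorderZoneConfig",
    "HeterogeneityField",
    "ParameterFields",
    "profile_D",
    "profile_alpha",
    "sample_heterogeneity",
    "build_parameter_fields",
    "coupling_term",
]

#: alpha is clamped strictly below 1 so ik1_scale stays in-domain
ALPHA_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Cell counts and cell size of the rectangular network."""

    nx: int
    ny: int
    nz: int = 1            # nz == 1 means a 2D sheet
    h: float = 0.025       # cell linear size, mm

    def __post_init__(self) -> None:
        if min(self.nx, self.ny) < 3 or self.nz < 1:
            raise ValueError("grid must be at least 3x3 cells")
        if self.h <= 0:
            raise ValueError("cell size h must be positive")

    @property
    def ndim(self) -> int:
        return 2 if self.nz == 1 else 3

    @property
    def shape(self) -> tuple:
        if self.nz == 1:
            return (self.ny, self.nx)
        return (self.ny, self.nx, self.nz)

    def y_coords(self) -> np.ndarray:
        """y coordinate (mm) of every cell row."""
        return np.arange(self.ny) * self.h


@dataclass(frozen=True)
class BorderZoneConfig:
    """Moving macroscopic profiles across the border zone.

    ``u`` is the signed border speed along y (negative moves the ramp
    toward the bottom of the grid).  The ramp width y2_0 - y1_0 stays
    constant in time.
    """

    D0: float              # diffusivity of the well-coupled layer, mm^2/ms
    Dmin: float            # diffusivity of the bottom layer, mm^2/ms
    alpha_top: float
    alpha_bottom: float
    y1_0: float            # initial lower limit of the steep ramp, mm
    y2_0: float            # initial upper limit, mm
    u: float = 0.0         # border speed, mm/ms
    ramp: Literal["linear", "smooth"] = "linear"

    def __post_init__(self) -> None:
        if self.y2_0 <= self.y1_0:
            raise ValueError("y2_0 must exceed y1_0")
        if not (self.D0 >= self.Dmin >= 0.0):
            raise ValueError("need D0 >= Dmin >= 0")
        for a in (self.alpha_top, self.alpha_bottom):
            if not (0.0 <= a < 1.0):
                raise ValueError("alpha limits must lie in [0, 1)")

    def y1(self, t: float) -> float:
        return self.y1_0 + self.u * t

    def y2(self, t: float) -> float:
        return self.y2_0 + self.u * t


def _ramp(y, lo_val: float, hi_val: float, y1: float, y2: float,
          shape: str) -> np.ndarray:
    """Clamped monotone ramp from lo_val (y<=y1) to hi_val (y>=y2)."""
    s = np.clip((np.asarray(y, dtype=float) - y1) / (y2 - y1), 0.0, 1.0)
    if shape == "smooth":
        s = s * s * (3.0 - 2.0 * s)
    # convex form hits the endpoint values exactly at s = 0 and s = 1
    return lo_val * (1.0 - s) + hi_val * s


def profile_D(y, t: float, cfg: BorderZoneConfig) -> np.ndarray:
    """Macroscopic diffusivity profile D(y, t)."""
    return _ramp(y, cfg.Dmin, cfg.D0, cfg.y1(t), cfg.y2(t), cfg.ramp)


def profile_alpha(y, t: float, cfg: BorderZoneConfig) -> np.ndarray:
    """Macroscopic excitability profile alpha(y, t)."""
    return _ramp(y, cfg.alpha_bottom, cfg.alpha_top,
                 cfg.y1(t), cfg.y2(t), cfg.ramp)


@dataclass(frozen=True)
class HeterogeneityField:
    """Frozen per-cell standard-normal deviates with intensity nu."""

    xi: np.ndarray
    nu: float
    seed: int


def sample_heterogeneity(grid: GridSpec, nu: float,
                         seed: int) -> HeterogeneityField:
    """Draw the frozen i.i.d. Gaussian heterogeneity field.

    The same (grid, seed) pair reproduces xi bitwise.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(grid.shape)
    return HeterogeneityField(xi=xi, nu=float(nu), seed=int(seed))


@dataclass
class ParameterFields:
    """Per-cell diffusivity and excitability at one instant."""

    D: np.ndarray            # mm^2/ms, >= 0
    alpha_cell: np.ndarray   # in [0, 1)

    def __post_init__(self) -> None:
        if self.D.shape != self.alpha_cell.shape:
            raise ValueError("D and alpha_cell shapes differ")
        if np.any(self.D < 0):
            raise ValueError("D must be non-negative")
        if np.any(self.alpha_cell < 0) or np.any(self.alpha_cell >= 1):
            raise ValueError("alpha_cell must lie in [0, 1)")


def build_parameter_fields(grid: GridSpec, cfg: BorderZoneConfig,
                           het: HeterogeneityField | None,
                           t: float = 0.0) -> ParameterFields:
    """Profiles evaluated on the grid plus heterogeneity, clamped.

    Heterogeneity perturbs alpha only; D keeps the macroscopic profile.
    """
    y = grid.y_coords()
    d_row = profile_D(y, t, cfg)
    a_row = profile_alpha(y, t, cfg)
    expand = (slice(None),) + (None,) * (len(grid.shape) - 1)
    D = np.broadcast_to(d_row[expand], grid.shape).copy()
    alpha = np.broadcast_to(a_row[expand], grid.shape).copy()
    if het is not None and het.nu > 0:
        if het.xi.shape != grid.shape:
            raise ValueError("heterogeneity field shape mismatch")
        alpha = alpha + het.nu * het.xi
    alpha = np.clip(alpha, 0.0, ALPHA_MAX)
    return ParameterFields(D=D, alpha_cell=alpha)


def interface_conductance(d_a: np.ndarray, d_b: np.ndarray,
                          rule: str = "arithmetic") -> np.ndarray:
    """Conductance of the contact between two neighbouring cells.

    A cell with D == 0 is fully isolated under either rule: the contact
    conductance vanishes whenever either side has zero diffusivity.
    """
    if rule == "arithmetic":
        g = 0.5 * (d_a + d_b)
        return np.where((d_a > 0) & (d_b > 0), g, 0.0)
    if rule == "harmonic":
        s = d_a + d_b
        return np.where((d_a > 0) & (d_b > 0),
                        2.0 * d_a * d_b / np.where(s > 0, s, 1.0), 0.0)
    raise ValueError(f"unknown conductance rule {rule!r}")


def coupling_term(v: np.ndarray, fields: ParameterFields, grid: GridSpec,
                  rule: str = "arithmetic") -> np.ndarray:
    """Discrete divergence-form coupling current at every cell, mV/ms.

    Flux form sum_j g_ij (V_j - V_i) / h^2 over nearest neighbours with
    no-flux outer boundaries; the grid sum therefore telescopes to zero
    for any input, and a D = 0 cell exchanges no current at all.
    """
    if v.shape != fields.D.shape:
        raise ValueError(
            f"voltage shape {v.shape} != parameter shape {fields.D.shape}")
    if v.shape != grid.shape:
        raise ValueError(f"field shape {v.shape} != grid shape {grid.shape}")
    out = np.zeros_like(v, dtype=float)
    inv_h2 = 1.0 / grid.h ** 2
    d = fields.D
    for axis in range(v.ndim):
        lo = [slice(None)] * v.ndim
        hi = [slice(None)] * v.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        g = interface_conductance(d[lo], d[hi], rule)
        flux = g * (v[hi] - v[lo]) * inv_h2   # flow from hi side into lo side
        out[lo] += flux
        out[hi] -= flux
    return out
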