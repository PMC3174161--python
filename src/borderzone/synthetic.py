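"""Analytic field fixtures with known singularity geometry.

Used to exercise the tip and filament detectors without running any
simulation: linear planes (exact intersection point), rigidly rotating
Archimedean spiral phase fields, their 3D extrusions (straight
filament), and scroll-ring torus phase fields (circular filament of
known length).  All fields are generated on integer cell grids and are
indexed like simulation fields (``[iy, ix]`` / ``[iy, ix, iz]``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_synthetic_fields"]


def _linear_planes(nx, ny, x0, y0, **_):
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return xx - x0, yy - y0, 0.0, 0.0


def _spiral(nx, ny, x0, y0, k=0.35, phase=0.0, chirality=-1, **_):
    """Archimedean spiral phase field tipped at (x0, y0).

    V = tanh(r) cos(chi), f = 0.5 + 0.5 tanh(r) sin(chi) with
    chi = chirality * theta - k r + phase; the V = 0 and f = 0.5
    isolines meet only at r = 0.
    """
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dx, dy = xx - x0, yy - y0
    r = np.hypot(dx, dy)
    chi = chirality * np.arctan2(dy, dx) - k * r + phase
    v = np.tanh(r) * np.cos(chi)
    f = 0.5 + 0.5 * np.tanh(r) * np.sin(chi)
    return v, f, 0.0, 0.5


def _extruded_spiral(nx, ny, nz, x0, y0, **kw):
    v2, f2, v_iso, f_iso = _spiral(nx, ny, x0, y0, **kw)
    v = np.repeat(v2[:, :, None], nz, axis=2)
    f = np.repeat(f2[:, :, None], nz, axis=2)
    return v, f, v_iso, f_iso


def _scroll_ring(nx, ny, nz, x0, y0, z0, ring_radius, phase=0.0, **_):
    """Scroll ring whose filament is the circle of radius ``ring_radius``
    around (x0, y0) in the plane z = z0."""
    yy, xx, zz = np.mgrid[0:ny, 0:nx, 0:nz].astype(float)
    rho = np.hypot(xx - x0, yy - y0)
    sig = np.hypot(rho - ring_radius, zz - z0)
    psi = np.arctan2(zz - z0, rho - ring_radius)
    v = np.tanh(sig) * np.cos(psi + phase)
    f = 0.5 + 0.5 * np.tanh(sig) * np.sin(psi + phase)
    return v, f, 0.0, 0.5


def make_synthetic_fields(kind: str, **kw):
    """Build an analytic fixture.

    Returns ``(v, f, v_iso, f_iso)``.  Kinds: ``linear-planes``,
    ``spiral``, ``extruded-spiral``, ``scroll-ring``.  Keyword arguments
    set grid sizes (nx, ny[, nz]), singularity position (x0, y0[, z0]),
    and per-kind geometry (k, phase, chirality, ring_radius).
    """
    kinds = {
        "linear-planes": _linear_planes,
        "spiral": _spiral,
        "extruded-spiral": _extruded_spiral,
        "scroll-ring": _scroll_ring,
    }
    if kind not in kinds:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**kw)
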