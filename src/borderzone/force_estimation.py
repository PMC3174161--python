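"""Empirical estimation of specific drift forces from direct simulations.

Three probes of a settled spiral, each measuring drift velocity of the
period-averaged core per unit perturbation:

* ``estimate_b2`` — advection term E dV/dx (electrophoretic drift); the
  complex slope of v(E) through the origin.  The equivalent
  filament-motion coefficient is B = -b2 (Re: tension, Im: binormal).
* ``estimate_grad_alpha_force`` — a shallow linear gradient of the
  excitability parameter alpha; the longitudinal (real) part is positive
  when the drift points toward higher alpha, the lateral (imaginary)
  part is positive counter-clockwise with respect to the gradient.
* ``estimate_inhomogeneity_curve`` — a disk of contrast delta-alpha at a
  set of distances; F_r > 0 means motion toward the disk centre,
  F_theta > 0 clockwise around it.

Velocities are in cells/ms and lengths in cell units throughout; the
probe geometry and conventions ride along with every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .brp_kinetics import CellParams
from .tissue_model import ALPHA_MAX, GridSpec, ParameterFields
from .simulator import (SimConfig, Tissue, initiate_spiral, uniform_fields)
from . import wave_analysis as wa

__all__ = [
    "SpecificForce",
    "ForceCurve",
    "SpiralPrep",
    "prepare_spiral",
    "measure_drift",
    "estimate_b2",
    "estimate_grad_alpha_force",
    "estimate_inhomogeneity_curve",
]


@dataclass
class SpecificForce:
    """Drift response per unit perturbation (complex, cells/ms per unit)."""

    value: complex
    uncertainty: float
    convention: str
    chirality: int
    residual: float = 0.0      # rel. deviation from linearity
    samples: list = field(default_factory=list)

    def conjugate(self) -> "SpecificForce":
        return replace(self, value=self.value.conjugate(),
                       chirality=-self.chirality)


@dataclass
class ForceCurve:
    """Distance-resolved interaction with a disk inhomogeneity.

    ``f_r[i]`` > 0: attraction toward the disk centre at distance
    ``d[i]``; ``f_theta[i]`` > 0: clockwise azimuthal drift.  Values are
    velocities per unit delta-alpha at probe radius ``r0`` (cells).
    """

    d: np.ndarray
    f_r: np.ndarray
    f_theta: np.ndarray
    sigma: np.ndarray
    r0: float
    delta_alpha: float
    chirality: int
    convention: str = ("F_r>0 toward centre; F_theta>0 clockwise; "
                       "velocity per unit delta_alpha at fixed r0")

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.f_r = np.asarray(self.f_r, dtype=float)
        self.f_theta = np.asarray(self.f_theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.f_r, self.f_theta)


@dataclass
class SpiralPrep:
    """A settled spiral ready for perturbation experiments."""

    grid: GridSpec
    params: CellParams
    cfg: SimConfig
    d_cells: float
    alpha0: float
    state: dict
    core: complex            # cell units
    period: float            # ms
    chirality: int


def prepare_spiral(alpha: float = 0.3, d_cells: float = 0.2, n: int = 100,
                   h: float = 0.025, dt: float = 0.05,
                   params: CellParams | None = None,
                   mirror: bool = False, cut_frac: float = 0.68,
                   settle: float = 400.0) -> SpiralPrep:
    """Initiate a spiral in a homogeneous box and settle it.

    The core position and rotation period are measured from one extra
    unperturbed stretch of about two rotations.
    """
    params = (params or CellParams()).with_alpha(alpha)
    grid = GridSpec(nx=n, ny=n, h=h)
    fields = uniform_fields(grid, d_cells, alpha)
    cfg = SimConfig(dt=dt, snapshot_stride=20)
    tis = Tissue(grid, fields, params, cfg)
    res = initiate_spiral(tis, mirror=mirror, cut_frac=cut_frac,
                          settle=settle)
    if not res.success:
        raise RuntimeError(f"spiral initiation failed: {res.message}")
    state = tis.state_dict()
    # unperturbed probe stretch for core position and period
    frames = []
    for _ in range(800):
        tis.step(20)
        frames.append((tis.t, tis.detect_tips()))
    tracks = sorted(wa.link_tracks(frames), key=lambda tr: -len(tr.t))
    if not tracks or tracks[0].duration < 500:
        raise RuntimeError("settled spiral lost during the probe stretch")
    tr = tracks[0]
    period = wa.estimate_period(tr)
    core = complex(np.mean(tr.x), np.mean(tr.y))
    return SpiralPrep(grid=grid, params=params, cfg=cfg, d_cells=d_cells,
                      alpha0=alpha, state=state, core=core, period=period,
                      chirality=res.chirality or tr.chirality)


def measure_drift(prep: SpiralPrep, e_advect: float = 0.0,
                  fields: ParameterFields | None = None,
                  n_periods: float = 5.0,
                  period_hint: float | None = None) -> wa.DriftEstimate:
    """Drift velocity of the prepared spiral under a perturbation.

    Restores the settled state, applies the advection magnitude and/or
    replacement parameter fields, runs ``n_periods`` rotations and fits
    the sliding period-averaged centre.  Raises if the spiral is lost
    (death or boundary collision).
    """
    cfg = replace(prep.cfg, e_advect=e_advect)
    base = fields if fields is not None else uniform_fields(
        prep.grid, prep.d_cells, prep.alpha0)
    tis = Tissue(prep.grid, base, prep.params, cfg)
    tis.load_state(prep.state)
    duration = n_periods * prep.period
    frames = []
    n_frames = int(round(duration / (cfg.dt * cfg.snapshot_stride)))
    for _ in range(n_frames):
        tis.step(cfg.snapshot_stride)
        frames.append((tis.t, tis.detect_tips()))
    tracks = sorted(wa.link_tracks(frames), key=lambda tr: -tr.duration)
    if not tracks or tracks[0].duration < 0.8 * duration:
        got = tracks[0].duration if tracks else 0.0
        raise RuntimeError(
            f"spiral lost during drift measurement "
            f"(track {got:.0f} ms of {duration:.0f} ms)")
    return wa.drift_velocity(tracks[0], period_hint)


def _complex_slope(xs: np.ndarray, vs: np.ndarray,
                   sigmas: np.ndarray) -> tuple[complex, float, float]:
    """Least-squares slope of complex v against real x through the origin."""
    xs = np.asarray(xs, dtype=float)
    vs = np.asarray(vs, dtype=complex)
    slope = np.sum(xs * vs) / np.sum(xs * xs)
    resid = vs - slope * xs
    scale = max(abs(slope) * np.max(np.abs(xs)), 1e-30)
    rel_resid = float(np.max(np.abs(resid)) / scale)
    dof = max(len(xs) - 1, 1)
    sig = math.sqrt((np.sum(np.abs(resid) ** 2) / dof
                     + np.sum(np.asarray(sigmas) ** 2) / len(xs))
                    / np.sum(xs * xs))
    return complex(slope), sig, rel_resid


def estimate_b2(prep: SpiralPrep,
                e_list=(-0.0005, -0.0002, 0.0002, 0.0005),
                n_periods: float = 5.0,
                nonlinearity_warn: float = 0.5) -> SpecificForce:
    """Specific force of the electrophoretic drift (curvature-equivalent).

    The drift velocity is measured per advection magnitude E and the
    complex slope through the origin is returned; the filament-motion
    coefficient is B = -b2.  E is in mm/ms; velocities are converted to
    the same length unit (mm) so b2 is dimensionless.
    """
    vs, sigs, samples = [], [], []
    h = prep.grid.h
    for e in e_list:
        est = measure_drift(prep, e_advect=e, n_periods=n_periods,
                            period_hint=prep.period)
        vs.append(est.velocity * h)     # cells/ms -> mm/ms
        sigs.append(est.uncertainty * h)
        samples.append({"E": e, "v_re": est.velocity.real,
                        "v_im": est.velocity.imag,
                        "sigma": est.uncertainty})
    slope, sig, rel = _complex_slope(np.asarray(e_list), vs, sigs)
    force = SpecificForce(
        value=slope, uncertainty=sig,
        convention=("b2: complex slope of v(E); Re along +x of the "
                    "advection, Im counter-clockwise; B = -b2"),
        chirality=prep.chirality, residual=rel, samples=samples)
    if rel > nonlinearity_warn:
        force.uncertainty = max(sig, rel * abs(slope))
    return force


def _gradient_fields(prep: SpiralPrep, grad: float) -> ParameterFields:
    """alpha = alpha0 + grad * (y - y_core) in cell units, clamped."""
    y = np.arange(prep.grid.ny, dtype=float) - prep.core.imag
    a_row = np.clip(prep.alpha0 + grad * y, 0.0, ALPHA_MAX)
    shape = prep.grid.shape
    expand = (slice(None),) + (None,) * (len(shape) - 1)
    alpha = np.broadcast_to(a_row[expand], shape).copy()
    d = np.full(shape, prep.d_cells * prep.grid.h ** 2)
    return ParameterFields(D=d, alpha_cell=alpha)


def estimate_grad_alpha_force(prep: SpiralPrep,
                              grad_list=(-0.001, -0.0005, 0.0005, 0.001),
                              n_periods: float = 5.0) -> SpecificForce:
    """Drift response to a shallow linear gradient of alpha (along +y).

    Returned complex value: real part is the longitudinal component
    (positive toward higher alpha), imaginary part the lateral component
    (positive counter-clockwise with respect to the gradient direction).
    Gradients are per cell; velocities per unit gradient, cells/ms.
    """
    vs, sigs, samples = [], [], []
    for g in grad_list:
        est = measure_drift(prep, fields=_gradient_fields(prep, g),
                            n_periods=n_periods, period_hint=prep.period)
        # gradient points along +y: longitudinal = v_y, lateral = -v_x
        c = est.velocity * np.exp(-1j * np.pi / 2.0)
        vs.append(c)
        sigs.append(est.uncertainty)
        samples.append({"grad": g, "v_re": est.velocity.real,
                        "v_im": est.velocity.imag,
                        "sigma": est.uncertainty})
    slope, sig, rel = _complex_slope(np.asarray(grad_list), vs, sigs)
    return SpecificForce(
        value=slope, uncertainty=sig,
        convention=("grad-alpha force: Re longitudinal (positive toward "
                    "higher alpha), Im lateral counter-clockwise"),
        chirality=prep.chirality, residual=rel, samples=samples)


def disk_fields(prep: SpiralPrep, delta_alpha: float, r0: float,
                centre: complex) -> ParameterFields:
    """Uniform background plus a disk of alpha contrast delta_alpha."""
    ny, nx = prep.grid.ny, prep.grid.nx
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (xx - centre.real) ** 2 + (yy - centre.imag) ** 2 <= r0 ** 2
    alpha = np.full((ny, nx), prep.alpha0)
    alpha[mask] = np.clip(prep.alpha0 + delta_alpha, 0.0, ALPHA_MAX)
    d = np.full((ny, nx), prep.d_cells * prep.grid.h ** 2)
    return ParameterFields(D=d, alpha_cell=alpha)


def estimate_inhomogeneity_curve(prep: SpiralPrep, delta_alpha: float,
                                 r0: float, d_list,
                                 n_periods: float = 4.0,
                                 direction: complex = 1.0 + 0.0j,
                                 subtract_baseline: bool = True,
                                 baseline: complex | None = None
                                 ) -> ForceCurve:
    """Interaction force with a disk inhomogeneity versus distance.

    For each distance d the disk is placed at ``core + d * direction``
    and the spiral's drift is measured over a few rotations; the radial
    (toward-centre positive) and azimuthal (clockwise positive)
    velocity components, divided by delta-alpha, give the curve.  The
    residual drift of the unperturbed spiral (lattice wobble, boundary
    bias) is measured once from the same snapshot and subtracted.
    """
    direction = direction / abs(direction)
    v_base = 0.0 + 0.0j
    if baseline is not None:
        v_base = complex(baseline)
    elif subtract_baseline:
        base = measure_drift(prep, n_periods=n_periods,
                             period_hint=prep.period)
        v_base = base.velocity
    f_r, f_t, sig = [], [], []
    for d in d_list:
        centre = prep.core + d * direction
        est = measure_drift(prep,
                            fields=disk_fields(prep, delta_alpha, r0,
                                               centre),
                            n_periods=n_periods, period_hint=prep.period)
        v = est.velocity - v_base
        u_r = direction                     # toward the centre
        radial = (v * np.conj(u_r)).real
        # clockwise azimuthal unit vector at the spiral position: with
        # the disk at +u_r, clockwise around the centre points along
        # +i*u_r when seen from the spiral (y up, angle decreasing)
        azim = (v * np.conj(1j * u_r)).real
        f_r.append(radial / delta_alpha)
        f_t.append(azim / delta_alpha)
        sig.append(est.uncertainty / abs(delta_alpha))
    return ForceCurve(d=np.asarray(d_list, dtype=float),
                      f_r=np.asarray(f_r), f_theta=np.asarray(f_t),
                      sigma=np.asarray(sig), r0=float(r0),
                      delta_alpha=float(delta_alpha),
                      chirality=prep.chirality)
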