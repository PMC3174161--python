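"""End-to-end border-zone protocols at desk scale.

The recovering ischaemic slab: an uncoupled, unexcitable bottom layer, a
well-coupled excitable top layer, and a moving transition band carrying
the coupling and excitability gradients plus frozen cellular
heterogeneity.  The alpha ramp is offset below the diffusivity ramp so
the band contains a weakly coupled, elevated-excitability layer where
heterogeneity seeds ectopic activity (the arrhythmogenic band).

Protocols: 2D/3D moving-border runs with online singularity tracking,
the escape curve (persistent spirals left behind versus border speed),
and deliberately arranged pinning experiments (drifting spiral plus
disk inhomogeneities) with a matched drift-ODE prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .brp_kinetics import CellParams
from .tissue_model import (ALPHA_MAX, BorderZoneConfig, GridSpec,
                           HeterogeneityField, ParameterFields,
                           build_parameter_fields, profile_D,
                           profile_alpha, sample_heterogeneity)
from .simulator import (SimConfig, Tissue, RunResult, run, uniform_fields,
                        measure_cv)
from . import wave_analysis as wa
from . import force_estimation as fe

__all__ = [
    "BorderProtocolConfig",
    "border_fields_at",
    "run_border_zone_2d",
    "run_border_zone_3d",
    "count_persistent",
    "escape_curve",
    "pinning_experiment",
]


@dataclass(frozen=True)
class BorderProtocolConfig:
    """Desk-scale moving border zone.

    Lengths are in cells (converted via ``h`` internally); the border
    speed ``u_cells`` is in cells/ms, negative moving toward the bottom
    (row 0).  ``alpha_shift`` displaces the alpha ramp below the
    diffusivity ramp, creating the weakly coupled high-excitability
    band.
    """

    nx: int = 48
    ny: int = 48
    nz: int = 1
    h: float = 0.025
    d_top: float = 0.2            # cell-units diffusivity of the top layer
    d_bottom: float = 0.0
    alpha_top: float = 0.35
    alpha_bottom: float = 0.0
    band_width: float = 12.0      # ramp width, cells
    alpha_shift: float = 14.0     # alpha ramp sits this far below D ramp
    nu: float = 0.18
    u_cells: float = -0.01
    y_start: float = None         # D-ramp lower limit at t=0 (cells)
    dt: float = 0.05
    duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u_cells >= 0:
            raise ValueError("the border must move toward the bottom "
                             "(u_cells < 0)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.nx, ny=self.ny, nz=self.nz, h=self.h)

    def d_config(self) -> BorderZoneConfig:
        y0 = self.y_start if self.y_start is not None else self.ny + 2.0
        return BorderZoneConfig(
            D0=self.d_top * self.h ** 2,
            Dmin=self.d_bottom * self.h ** 2,
            alpha_top=self.alpha_top, alpha_bottom=self.alpha_bottom,
            y1_0=y0 * self.h, y2_0=(y0 + self.band_width) * self.h,
            u=self.u_cells * self.h)

    def alpha_config(self) -> BorderZoneConfig:
        base = self.d_config()
        shift = self.alpha_shift * self.h
        return replace(base, y1_0=base.y1_0 - shift,
                       y2_0=base.y2_0 - shift)

    def crossing_time(self) -> float:
        """Time for both ramps to exit through the bottom of the box."""
        start = (self.y_start if self.y_start is not None
                 else self.ny + 2.0)
        travel = start + self.band_width + self.alpha_shift + 2.0
        return travel / abs(self.u_cells)


def border_fields_at(cfg: BorderProtocolConfig,
                     het: HeterogeneityField):
    """Time-dependent ParameterFields factory for the moving border."""
    grid = cfg.grid
    d_cfg = cfg.d_config()
    a_cfg = cfg.alpha_config()
    y = grid.y_coords()
    expand = (slice(None),) + (None,) * (len(grid.shape) - 1)

    def fields(t: float) -> ParameterFields:
        d_row = profile_D(y, t, d_cfg)
        a_row = profile_alpha(y, t, a_cfg)
        d = np.broadcast_to(d_row[expand], grid.shape).copy()
        alpha = np.broadcast_to(a_row[expand], grid.shape).copy()
        if het is not None and het.nu > 0:
            alpha = alpha + het.nu * het.xi
        return ParameterFields(D=d, alpha_cell=np.clip(alpha, 0.0,
                                                       ALPHA_MAX))
    return fields


def run_border_zone_2d(cfg: BorderProtocolConfig,
                       params: CellParams | None = None,
                       extra_time: float = 600.0,
                       snapshot_stride: int = 40) -> RunResult:
    """Moving-border 2D run with online tip tracking.

    Runs until the border has crossed the whole box plus ``extra_time``
    of follow-up in the recovered (homogeneous, well-coupled) medium.
    """
    if cfg.nz != 1:
        raise ValueError("use run_border_zone_3d for nz > 1")
    params = params or CellParams()
    grid = cfg.grid
    het = sample_heterogeneity(grid, cfg.nu, cfg.seed)
    fields_at = border_fields_at(cfg, het)
    sim = SimConfig(dt=cfg.dt, snapshot_stride=snapshot_stride,
                    seed=cfg.seed, settle_time=0.0)
    tis = Tissue(grid, fields_at(0.0), params, sim)
    duration = (cfg.duration if cfg.duration is not None
                else cfg.crossing_time() + extra_time)
    result = run(tis, duration, fields_at=fields_at,
                 field_update_every=5.0, detect=True)
    result.events.append(("border_exit", cfg.crossing_time()))
    return result


def run_border_zone_3d(cfg: BorderProtocolConfig,
                       params: CellParams | None = None,
                       extra_time: float = 600.0,
                       snapshot_every: float = 50.0):
    """Moving-border 3D run with filament extraction per snapshot.

    Returns ``(RunResult, filament_history)`` where the history is a
    list of ``(t, [Filament])``.
    """
    if cfg.nz < 2:
        raise ValueError("3D protocol needs nz >= 2")
    params = params or CellParams()
    grid = cfg.grid
    het = sample_heterogeneity(grid, cfg.nu, cfg.seed)
    fields_at = border_fields_at(cfg, het)
    sim = SimConfig(dt=cfg.dt, snapshot_stride=200, seed=cfg.seed)
    tis = Tissue(grid, fields_at(0.0), params, sim)
    duration = (cfg.duration if cfg.duration is not None
                else cfg.crossing_time() + extra_time)
    history = []
    next_snap = [snapshot_every]

    def on_frame(t: Tissue) -> None:
        if t.t >= next_snap[0]:
            fils = wa.extract_filaments(t.v, t.gates["f"],
                                        sim.v_iso, sim.f_iso)
            history.append((t.t, fils))
            next_snap[0] += snapshot_every

    result = run(tis, duration, fields_at=fields_at,
                 field_update_every=5.0, detect=False, on_frame=on_frame)
    result.events.append(("border_exit", cfg.crossing_time()))
    return result, history


def count_persistent(result: RunResult, t_after: float,
                     period: float = 250.0) -> int:
    """Persistent spiral count after the border has left the box."""
    return wa.count_spirals(result.tracks, t_after=t_after, period=period)


def escape_curve(speed_list, seeds, cfg: BorderProtocolConfig,
                 params: CellParams | None = None,
                 period: float = 250.0):
    """Mean persistent-spiral count versus border speed.

    Also reports the plane-wave conduction velocity of the top layer as
    the upper reference scale for border speeds.  Returns a list of dict
    rows (speed, mean, se, counts).
    """
    params = params or CellParams()
    cv = measure_cv(cfg.d_top, cfg.alpha_top, params, nx=120,
                    dt=cfg.dt, max_time=1500.0)
    rows = []
    for u in speed_list:
        if u >= 0:
            raise ValueError("border speeds must be negative (downward)")
        counts = []
        for seed in seeds:
            c = replace(cfg, u_cells=u, seed=int(seed))
            result = run_border_zone_2d(c, params=params)
            counts.append(count_persistent(result, c.crossing_time(),
                                           period=period))
        counts = np.asarray(counts, dtype=float)
        rows.append({
            "speed": float(u),
            "mean": float(np.mean(counts)),
            "se": float(np.std(counts) / math.sqrt(len(counts))),
            "counts": counts.tolist(),
        })
    return {"rows": rows,
            "cv_cells": cv.cv_cells,
            "period": period}


@dataclass
class PinningOutcome:
    classification: str          # free-drift | temporary-stall | pinned
    track: wa.TipTrajectory
    centre_t: np.ndarray
    centre: np.ndarray
    terminal_speed: float
    min_speed: float
    ode_trajectory: object = None


def _centre_series(track: wa.TipTrajectory, period: float):
    dt = float(np.median(np.diff(track.t)))
    tu = np.arange(track.t[0], track.t[-1], dt)
    zu = np.interp(tu, track.t, track.x) + 1j * np.interp(
        tu, track.t, track.y)
    w = max(2, int(round(period / dt)))
    kern = np.ones(w) / w
    centre = np.convolve(zu, kern, mode="valid")
    tc = tu[w - 1:] - (w - 1) * dt / 2.0
    return tc, centre


def pinning_experiment(disks, e_advect: float,
                       prep: fe.SpiralPrep | None = None,
                       alpha: float = 0.3, d_cells: float = 0.2,
                       n: int = 100, duration: float = 2200.0,
                       reference_speed: float | None = None,
                       stall_fraction: float = 0.5,
                       recover_fraction: float = 0.55,
                       pin_fraction: float = 0.3,
                       drift_model=None) -> PinningOutcome:
    """Drifting spiral meeting deliberately arranged disk inhomogeneities.

    ``disks`` is a list of ``(position_offset, delta_alpha, radius)``
    with positions relative to the settled core (complex, cells).  The
    spiral is dragged by the advection term ``e_advect``.  The outcome
    is classified from the smoothed speed of the period-averaged centre
    against ``reference_speed`` (the free-drift speed under the same
    drag; measured on the fly when not given):

    * ``pinned`` — terminal speed below ``pin_fraction`` of the free
      speed and the final centre within capture range of a disk,
    * ``temporary-stall`` — an interior slowdown below
      ``stall_fraction`` of the free speed with subsequent recovery,
    * ``free-drift`` — neither.

    The analysis window is truncated when the centre approaches an
    outer boundary, where wall interactions would masquerade as pinning.
    """
    if prep is None:
        prep = fe.prepare_spiral(alpha=alpha, d_cells=d_cells, n=n)
    base = uniform_fields(prep.grid, prep.d_cells, prep.alpha0)
    alpha_cell = base.alpha_cell.copy()
    ny, nx = prep.grid.ny, prep.grid.nx
    yy, xx = np.mgrid[0:ny, 0:nx]
    for offset, da, r0 in disks:
        c = prep.core + offset
        mask = (xx - c.real) ** 2 + (yy - c.imag) ** 2 <= r0 ** 2
        alpha_cell[mask] = np.clip(alpha_cell[mask] + da, 0.0, ALPHA_MAX)
    fields = ParameterFields(D=base.D, alpha_cell=alpha_cell)

    cfg = replace(prep.cfg, e_advect=e_advect)
    tis = Tissue(prep.grid, fields, prep.params, cfg)
    tis.load_state(prep.state)
    frames = []
    n_frames = int(round(duration / (cfg.dt * cfg.snapshot_stride)))
    for _ in range(n_frames):
        tis.step(cfg.snapshot_stride)
        frames.append((tis.t, tis.detect_tips()))
    tracks = sorted(wa.link_tracks(frames), key=lambda tr: -tr.duration)
    if not tracks:
        raise RuntimeError("spiral lost during the pinning experiment")
    track = tracks[0]
    tc, centre = _centre_series(track, prep.period)
    # truncate once the centre gets close to a wall
    margin = 14.0
    inside = ((centre.real > margin) & (centre.real < nx - margin)
              & (centre.imag > margin) & (centre.imag < ny - margin))
    if np.any(~inside):
        cut = int(np.argmax(~inside))
        if cut > 10:
            tc, centre = tc[:cut], centre[:cut]
    # smoothed speed over ~1.5 rotation periods
    dtc = float(np.median(np.diff(tc)))
    w = max(2, int(round(1.5 * prep.period / dtc)))
    if len(centre) < 2 * w:
        raise RuntimeError("pinning run too short for speed analysis")
    speed = np.abs(centre[w:] - centre[:-w]) / (tc[w:] - tc[:-w])
    terminal = float(np.mean(speed[-max(1, w // 3):]))
    smin = float(np.min(speed[w // 2:]))
    free = float(reference_speed) if reference_speed is not None \
        else float(np.median(speed[:w]))

    near_disk = False
    if disks:
        dists = [abs(centre[-1] - (prep.core + off))
                 for off, _, r0 in disks]
        near_disk = min(d - r0 for d, (_, _, r0)
                        in zip(dists, disks)) < 14.0
    if terminal < pin_fraction * free and (near_disk or not disks):
        label = "pinned"
    elif smin < stall_fraction * free and \
            terminal > recover_fraction * free:
        label = "temporary-stall"
    else:
        label = "free-drift"

    ode_tr = None
    if drift_model is not None:
        from .drift_ode import integrate_drift
        ode_tr = integrate_drift(drift_model,
                                 prep.core - (prep.core + disks[0][0]),
                                 duration)
    return PinningOutcome(classification=label, track=track,
                          centre_t=tc, centre=centre,
                          terminal_speed=terminal, min_speed=smin,
                          ode_trajectory=ode_tr)
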