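"""Explicit 2D/3D time stepping of the coupled Beeler-Reuter-Pumir network.

Gates advance by the exponential Rush-Larsen update, voltage and calcium
by forward Euler.  The voltage equation receives the ionic currents, the
divergence-form coupling operator, an optional advection perturbation
``E dV/dx`` (the electrophoretic term used to probe curvature-equivalent
drift), and external stimulus current.  All outer boundaries are no-flux.

Voltage-dependent rate expressions are evaluated through a dense lookup
table with linear interpolation (0.01 mV spacing), which is the hot path;
``brp_kinetics`` holds the reference expressions the table is built from.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .brp_kinetics import (CellParams, CellState, GATE_NAMES, cell_rhs,
                           find_rest_state, gate_rates, gate_steady_state,
                           initial_state)
from .tissue_model import (GridSpec, ParameterFields, interface_conductance)
from . import wave_analysis as wa
from . import _kernels as _K

__all__ = [
    "SimConfig",
    "RunResult",
    "Tissue",
    "step_tissue",
    "uniform_fields",
    "edge_stimulus",
    "half_plane_stimulus",
    "measure_cv",
    "initiate_spiral",
    "calibrate_isovalues",
    "probe_regime",
    "run",
]

UPSTROKE_THRESHOLD = -30.0   # mV, used for activation detection


@dataclass(frozen=True)
class SimConfig:
    """Time-stepping and measurement settings."""

    dt: float = 0.05             # ms
    duration: float = 1000.0     # ms
    snapshot_stride: int = 40    # steps between tip detections
    e_advect: float = 0.0        # advection magnitude, mm/ms (applied to V)
    cfl_safety: float = 0.9
    v_iso: float = -30.0         # tip-detection isoline of V, mV
    f_iso: float = 0.5           # tip-detection isoline of the f gate
    settle_time: float = 0.0     # ignore activity before this, ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class _RateTables:
    """Dense tables of the voltage-dependent factors used per step.

    Rows: per gate g_inf and exp(-dt (a+b)); then the unscaled i_K1(V)
    and the x1-current coefficient.  Linear interpolation on a 0.01 mV
    grid keeps the error far below the time-discretization error.
    """

    V_MIN, V_MAX, DV = -150.0, 150.0, 0.01

    def __init__(self, dt: float, params: CellParams):
        self.dt = dt
        vg = np.arange(self.V_MIN, self.V_MAX + self.DV, self.DV)
        rates = gate_rates(vg, params)
        rows = []
        for g in GATE_NAMES:
            a, b = rates[g]
            rows.append(a / (a + b))
            rows.append(np.exp(-dt * (a + b)))
        e = np.exp
        ik1_full = 0.35 * (
            4.0 * (e(0.04 * (vg + 85.0)) - 1.0)
            / (e(0.08 * (vg + 53.0)) + e(0.04 * (vg + 53.0)))
            + 0.2 * np.where(np.abs(vg + 23.0) < 1e-9, 25.0,
                             (vg + 23.0) / (1.0 - e(-0.04 * (vg + 23.0))))
        )
        rows.append(ik1_full)
        rows.append(0.8 * (e(0.04 * (vg + 77.0)) - 1.0)
                    / e(0.04 * (vg + 35.0)))
        self.table = np.ascontiguousarray(np.asarray(rows))
        self.n = self.table.shape[1]

    def eval(self, v: np.ndarray) -> np.ndarray:
        """All 14 rows interpolated at voltages v; shape (14,) + v.shape."""
        idx = (v - self.V_MIN) * (1.0 / self.DV)
        idx = np.clip(idx, 0.0, self.n - 1.001)
        i0 = idx.astype(np.int64)
        w = idx - i0
        t = self.table
        return t[:, i0] * (1.0 - w) + t[:, i0 + 1] * w


_tables_cache: dict[tuple, _RateTables] = {}


def _get_tables(dt: float, params: CellParams) -> _RateTables:
    key = (round(dt, 12), params.x1_speedup, params.d_speedup,
           params.f_speedup)
    if key not in _tables_cache:
        _tables_cache[key] = _RateTables(dt, params)
    return _tables_cache[key]


_rest_cache: dict[tuple, tuple] = {}


def _table_rest(tables: _RateTables, params: CellParams,
                max_iter: int = 80000) -> tuple:
    """Fixed point of the table-driven single-cell map.

    The lookup tables approximate the rate functions to ~1e-6, so the
    discrete dynamics has its own rest state a hair away from the exact
    one; starting tissues there keeps a uniform quiescent grid frozen to
    machine precision.  Cached per (dt, kinetics, alpha).
    """
    key = (round(tables.dt, 12), params.x1_speedup, params.d_speedup,
           params.f_speedup, params.alpha, params.k_k1_base, params.g_na,
           params.g_s)
    if key in _rest_cache:
        return _rest_cache[key]
    rest = find_rest_state(params)
    base = rest.state if rest.state is not None else initial_state()
    v = np.array([float(base.v)])
    ca = np.array([float(base.ca)])
    gates = {g: np.array([float(getattr(base, g))]) for g in GATE_NAMES}
    k1s = params.k_k1_base * (1.0 - params.alpha)
    dt = tables.dt
    for it in range(max_iter):
        vals = tables.eval(v)
        i_k1 = k1s * vals[12]
        i_x1 = gates["x1"] * vals[13]
        i_na = (params.g_na * gates["m"] ** 3 * gates["h"] * gates["j"]
                + params.g_nac) * (v - params.e_na)
        e_s = -82.3 - 13.0287 * np.log(ca)
        i_s = params.g_s * gates["d"] * gates["f"] * (v - e_s)
        v_new = v + dt * (-(i_k1 + i_x1 + i_na + i_s) / params.c_m)
        ca = np.maximum(ca + dt * (-1e-7 * i_s + 0.07 * (1e-7 - ca)),
                        1e-12)
        for k, g in enumerate(GATE_NAMES):
            g_inf, fac = vals[2 * k], vals[2 * k + 1]
            gates[g] = g_inf + (gates[g] - g_inf) * fac
        if it > 100 and abs(float(v_new[0] - v[0])) < 1e-14:
            v = v_new
            break
        v = v_new
    out = (float(v[0]), float(ca[0]),
           {g: float(gates[g][0]) for g in GATE_NAMES})
    _rest_cache[key] = out
    return out


def uniform_fields(grid: GridSpec, d_cells: float,
                   alpha: float | np.ndarray) -> ParameterFields:
    """Homogeneous (or explicitly given per-cell alpha) parameter fields.

    ``d_cells`` is the diffusivity in cell units D/h^2 (1/ms); the stored
    D is in mm^2/ms for the given grid spacing.
    """
    d = np.full(grid.shape, d_cells * grid.h ** 2, dtype=float)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), grid.shape).copy()
    return ParameterFields(D=d, alpha_cell=a)


class Tissue:
    """Mutable simulation state of one cell network."""

    def __init__(self, grid: GridSpec, fields: ParameterFields,
                 params: CellParams, cfg: SimConfig):
        self.grid = grid
        self.fields = fields
        self.params = params
        self.cfg = cfg
        self.t = 0.0
        self._check_cfl()
        self.tables = _get_tables(cfg.dt, params)
        self._tableT = None
        self._build_coupling()
        self._k1_scale = params.k_k1_base * (1.0 - fields.alpha_cell)
        v0, ca0, gates0 = _table_rest(self.tables, params)
        shp = grid.shape
        self.v = np.full(shp, v0)
        self.ca = np.full(shp, ca0)
        self.gates = {g: np.full(shp, gates0[g]) for g in GATE_NAMES}
        self.upstroke_count = np.zeros(shp, dtype=np.int32)
        self._above = self.v >= UPSTROKE_THRESHOLD

    # -- setup ---------------------------------------------------------

    def _check_cfl(self) -> None:
        dmax = float(np.max(self.fields.D))
        if dmax > 0:
            bound = self.grid.h ** 2 / (2.0 * self.grid.ndim * dmax)
            if self.cfg.dt > self.cfg.cfl_safety * bound:
                raise ValueError(
                    f"dt={self.cfg.dt} violates the diffusion stability "
                    f"bound {self.cfg.cfl_safety * bound:.4g} ms "
                    f"(h={self.grid.h}, max D={dmax:.4g})")

    def _build_coupling(self) -> None:
        """Precompute interface conductances / h^2 along each axis."""
        d = self.fields.D
        inv_h2 = 1.0 / self.grid.h ** 2
        self._g = []
        for axis in range(d.ndim):
            lo = [slice(None)] * d.ndim
            hi = [slice(None)] * d.ndim
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            g = interface_conductance(d[tuple(lo)], d[tuple(hi)]) * inv_h2
            self._g.append(g)

    def set_fields(self, fields: ParameterFields) -> None:
        """Swap in new parameter fields (moving border zone)."""
        self.fields = fields
        self._build_coupling()
        self._k1_scale = self.params.k_k1_base * (1.0 - fields.alpha_cell)

    # -- state snapshot ------------------------------------------------

    def state_dict(self) -> dict:
        d = {"v": self.v.copy(), "ca": self.ca.copy(), "t": self.t,
             "upstroke_count": self.upstroke_count.copy()}
        d.update({g: arr.copy() for g, arr in self.gates.items()})
        return d

    def load_state(self, d: dict) -> None:
        self.v = d["v"].copy()
        self.ca = d["ca"].copy()
        self.t = float(d["t"])
        self.upstroke_count = d["upstroke_count"].copy().astype(np.int32)
        self.gates = {g: d[g].copy() for g in GATE_NAMES}
        self._above = self.v >= UPSTROKE_THRESHOLD

    def save_checkpoint(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_checkpoint(self, path) -> None:
        with np.load(path) as z:
            self.load_state({k: z[k] for k in z.files})

    @property
    def f_gate(self) -> np.ndarray:
        return self.gates["f"]

    # -- stepping ------------------------------------------------------

    def _coupling(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        for axis, g in enumerate(self._g):
            lo = [slice(None)] * v.ndim
            hi = [slice(None)] * v.ndim
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            flux = g * (v[hi] - v[lo])
            out[lo] += flux
            out[hi] -= flux
        return out

    def step(self, n_steps: int = 1,
             i_ext: Callable[[float], np.ndarray | float] | None = None
             ) -> None:
        """Advance the tissue by ``n_steps`` explicit steps."""
        if _K.HAVE_NUMBA:
            self._step_numba(n_steps, i_ext)
        else:
            self._step_numpy(n_steps, i_ext)

    def _as3d(self, a: np.ndarray) -> np.ndarray:
        return a if a.ndim == 3 else a.reshape(a.shape + (1,))

    def _step_numba(self, n_steps: int, i_ext) -> None:
        dt = self.cfg.dt
        p = self.params
        v = self._as3d(self.v)
        ca = self._as3d(self.ca)
        gates = {g: self._as3d(arr) for g, arr in self.gates.items()}
        k1s = self._as3d(self._k1_scale)
        if v.ndim == 3 and len(self._g) == 3:
            gy, gx, gz = (self._as3d(g) for g in self._g)
        else:
            gy, gx = self._as3d(self._g[0]), self._as3d(self._g[1])
            gz = np.zeros(v.shape[:2] + (0,))
        table = self.tables.table.T.copy() if self._tableT is None \
            else self._tableT
        self._tableT = table
        e_over_2h = self.cfg.e_advect / (2.0 * self.grid.h)
        v_out = np.empty_like(v)
        dummy = np.zeros((1, 1, 1))
        for _ in range(n_steps):
            stim = i_ext(self.t) if i_ext is not None else 0.0
            has_stim = not np.isscalar(stim) or stim != 0.0
            stim_arr = self._as3d(np.broadcast_to(
                np.asarray(stim, dtype=float), self.grid.shape).copy()) \
                if has_stim else dummy
            _K.step_kernel(v, ca, gates["m"], gates["h"], gates["j"],
                           gates["d"], gates["f"], gates["x1"], k1s,
                           gy, gx, gz, table,
                           self.tables.V_MIN, 1.0 / self.tables.DV, dt,
                           e_over_2h, stim_arr, has_stim,
                           p.g_na, p.g_nac, p.e_na, p.g_s, 1.0 / p.c_m,
                           v_out)
            v, v_out = v_out, v
            self.t += dt
            vv = v.reshape(self.grid.shape)
            if not np.all(np.isfinite(vv)):
                bad = np.argwhere(~np.isfinite(vv))[0]
                raise FloatingPointError(
                    f"NaN/Inf voltage at t={self.t:.3f} ms, "
                    f"cell {tuple(bad)}")
            above = vv >= UPSTROKE_THRESHOLD
            if self.t >= self.cfg.settle_time:
                self.upstroke_count += (~self._above & above)
            self._above = above
        self.v = v.reshape(self.grid.shape)
        self.ca = ca.reshape(self.grid.shape)
        self.gates = {g: arr.reshape(self.grid.shape)
                      for g, arr in gates.items()}

    def _step_numpy(self, n_steps: int, i_ext) -> None:
        dt = self.cfg.dt
        p = self.params
        e_adv = self.cfg.e_advect
        for _ in range(n_steps):
            v = self.v
            vals = self.tables.eval(v)
            i_k1 = self._k1_scale * vals[12]
            i_x1 = self.gates["x1"] * vals[13]
            m, h, j = self.gates["m"], self.gates["h"], self.gates["j"]
            dg, fg = self.gates["d"], self.gates["f"]
            i_na = (p.g_na * m * m * m * h * j + p.g_nac) * (v - p.e_na)
            e_s = -82.3 - 13.0287 * np.log(self.ca)
            i_s = p.g_s * dg * fg * (v - e_s)
            dv = -(i_k1 + i_x1 + i_na + i_s) / p.c_m
            dv += self._coupling(v)
            if e_adv != 0.0:
                dv += e_adv * np.gradient(v, self.grid.h, axis=1)
            if i_ext is not None:
                dv = dv + i_ext(self.t)
            self.v = v + dt * dv
            self.ca = np.maximum(
                self.ca + dt * (-1.0e-7 * i_s + 0.07 * (1.0e-7 - self.ca)),
                1e-12)
            for k, g in enumerate(GATE_NAMES):
                g_inf, fac = vals[2 * k], vals[2 * k + 1]
                self.gates[g] = g_inf + (self.gates[g] - g_inf) * fac
            self.t += dt
            if not np.all(np.isfinite(self.v)):
                bad = np.argwhere(~np.isfinite(self.v))[0]
                raise FloatingPointError(
                    f"NaN/Inf voltage at t={self.t:.3f} ms, cell {tuple(bad)}")
            above = self.v >= UPSTROKE_THRESHOLD
            if self.t >= self.cfg.settle_time:
                self.upstroke_count += (~self._above & above)
            self._above = above

    def detect_tips(self) -> list:
        if self.grid.ndim != 2:
            raise ValueError("detect_tips requires a 2D tissue")
        return wa.detect_tips(self.v, self.f_gate, self.cfg.v_iso,
                              self.cfg.f_iso, t=self.t)


def step_tissue(tissue: Tissue, n_steps: int = 1, i_ext=None) -> Tissue:
    """Functional wrapper over :meth:`Tissue.step`."""
    tissue.step(n_steps, i_ext)
    return tissue


def reference_step(tissue: Tissue, i_ext=None) -> None:
    """One step via the reference kinetics path (no tables); for testing."""
    from .tissue_model import coupling_term
    dt = tissue.cfg.dt
    p = tissue.params
    state = CellState(v=tissue.v, ca=tissue.ca, **tissue.gates)
    from .brp_kinetics import currents
    cur = currents(state, replace(p, alpha=0.0))
    i_k1 = tissue._k1_scale * cur["i_k1"] / p.k_k1_base
    i_ion = i_k1 + cur["i_x1"] + cur["i_na"] + cur["i_s"]
    dv = -i_ion / p.c_m + coupling_term(tissue.v, tissue.fields, tissue.grid)
    if tissue.cfg.e_advect:
        dv += tissue.cfg.e_advect * np.gradient(tissue.v, tissue.grid.h,
                                                axis=1)
    if i_ext is not None:
        dv = dv + i_ext(tissue.t)
    v_new = tissue.v + dt * dv
    ca_new = np.maximum(tissue.ca + dt * (-1e-7 * cur["i_s"]
                                          + 0.07 * (1e-7 - tissue.ca)), 1e-12)
    rates = gate_rates(tissue.v, tissue.params)
    for g, (a, b) in rates.items():
        g_inf = a / (a + b)
        tissue.gates[g] = g_inf + (tissue.gates[g] - g_inf) * np.exp(
            -dt * (a + b))
    tissue.v = v_new
    tissue.ca = ca_new
    tissue.t += dt


# -- stimulation helpers ----------------------------------------------


def edge_stimulus(grid: GridSpec, amplitude: float, duration: float,
                  t_on: float = 0.0, axis: int = 1, width: int = 3,
                  side: str = "low") -> Callable[[float], np.ndarray | float]:
    """Stimulus current on a band of cells at one face of the grid."""
    mask = np.zeros(grid.shape)
    sl = [slice(None)] * len(grid.shape)
    sl[axis] = slice(None, width) if side == "low" else slice(-width, None)
    mask[tuple(sl)] = amplitude
    def f(t: float):
        return mask if t_on <= t < t_on + duration else 0.0
    return f


def half_plane_stimulus(grid: GridSpec, amplitude: float, duration: float,
                        t_on: float, axis: int = 0, side: str = "low"
                        ) -> Callable[[float], np.ndarray | float]:
    mask = np.zeros(grid.shape)
    n = grid.shape[axis]
    sl = [slice(None)] * len(grid.shape)
    sl[axis] = slice(None, n // 2) if side == "low" else slice(n // 2, None)
    mask[tuple(sl)] = amplitude
    def f(t: float):
        return mask if t_on <= t < t_on + duration else 0.0
    return f


# -- measurements ------------------------------------------------------


@dataclass
class CVResult:
    cv: float | None         # mm/ms, None when no propagation
    cv_cells: float | None   # cells/ms
    message: str = ""


def measure_cv(d_cells: float, alpha: float, params: CellParams,
               nx: int = 200, h: float = 0.025, dt: float = 0.05,
               max_time: float = 2500.0,
               stim_amplitude: float | None = None) -> CVResult:
    """Plane-wave conduction velocity in a thin strip.

    Timing planes at 40% and 80% of the strip length, away from the
    stimulated edge and the far boundary.
    """
    grid = GridSpec(nx=nx, ny=3, h=h)
    fields = uniform_fields(grid, d_cells, alpha)
    cfg = SimConfig(dt=dt, duration=max_time)
    tis = Tissue(grid, fields, params, cfg)
    amp = stim_amplitude if stim_amplitude is not None \
        else params.stim_amplitude
    width = max(3, int(round(3.0 * math.sqrt(max(d_cells, 1.0)))))
    stim = edge_stimulus(grid, amp, params.stim_duration, axis=1,
                         width=width)
    x1, x2 = int(0.4 * nx), int(0.8 * nx)
    t1 = t2 = None
    n_steps = int(max_time / dt)
    check = max(1, int(0.1 / dt))
    prev = (tis.t, tis.v[1, x1], tis.v[1, x2])
    thr = UPSTROKE_THRESHOLD
    for k in range(0, n_steps, check):
        tis.step(check, stim)
        v1, v2 = tis.v[1, x1], tis.v[1, x2]
        t_prev, p1, p2 = prev
        # sub-sample crossing time by linear interpolation
        if t1 is None and v1 > thr:
            t1 = t_prev + (tis.t - t_prev) * (thr - p1) / (v1 - p1)
        if v2 > thr:
            t2 = t_prev + (tis.t - t_prev) * (thr - p2) / (v2 - p2)
            break
        prev = (tis.t, v1, v2)
        if t1 is None and tis.t > 0.6 * max_time:
            break
    if t1 is None or t2 is None or t2 <= t1:
        return CVResult(None, None, "no propagation")
    cv = (x2 - x1) * h / (t2 - t1)
    return CVResult(cv=cv, cv_cells=cv / h)


def calibrate_isovalues(params: CellParams, alpha: float,
                        dt: float = 0.02) -> tuple[float, float]:
    """Default tip isolines: V at mid-upstroke of a single-cell AP, f = 0.5."""
    from .brp_kinetics import simulate_cell
    p = params.with_alpha(alpha)
    rest = find_rest_state(p)
    v0 = float(rest.state.v) if rest.state is not None else -80.0
    _, v = simulate_cell(p, 500.0, dt=dt, stim_times=(20.0,))
    return 0.5 * (v0 + float(np.max(v))), 0.5


# -- spiral initiation -------------------------------------------------


@dataclass
class InitiationResult:
    success: bool
    n_tips: int
    chirality: int | None
    message: str = ""


def initiate_spiral(tissue: Tissue, s1_amplitude: float = 30.0,
                    s1_duration: float = 2.0,
                    s2_amplitude: float = 30.0, s2_duration: float = 5.0,
                    s2_delay: float | None = None,
                    mirror: bool = False,
                    monitor_frac: float = 0.35,
                    mode: str = "cut",
                    cut_frac: float = 0.55,
                    settle: float = 150.0) -> InitiationResult:
    """Cross-field S1-S2 initiation of a single spiral.

    S1 launches a plane wave from the low-x face; S2 stimulates the low-y
    (or, mirrored, high-y) half-plane inside the vulnerable window.  When
    ``s2_delay`` is None, S2 fires when the monitor cell (mid-height, at
    ``monitor_frac`` of the width) has repolarized through the tip isoline
    after the S1 passage; the phase singularity then forms near that
    point, leaving room for the spiral to curl.
    """
    grid = tissue.grid
    s1 = edge_stimulus(grid, s1_amplitude, s1_duration, t_on=tissue.t,
                       axis=1)
    t_limit = tissue.t + 3000.0
    dt_chunk = max(1, int(1.0 / tissue.cfg.dt))

    if mode == "cut":
        # run S1 until the wavefront reaches cut_frac of the width, then
        # reset one half-plane to rest: the surviving half-front curls
        probe = (grid.ny // 2, int(grid.nx * cut_frac))
        while tissue.t < t_limit:
            tissue.step(dt_chunk, s1)
            if tissue.v[probe] > UPSTROKE_THRESHOLD:
                break
        else:
            return InitiationResult(False, 0, None,
                                    "S1 never reached the cut point")
        rest = find_rest_state(tissue.params)
        base = rest.state if rest.state is not None else initial_state()
        half = slice(None, grid.ny // 2) if not mirror \
            else slice(grid.ny // 2, None)
        tissue.v[half] = float(base.v)
        tissue.ca[half] = float(base.ca)
        for g in GATE_NAMES:
            tissue.gates[g][half] = float(getattr(base, g))
    else:
        centre = (grid.ny // 2, int(grid.nx * monitor_frac))
        excited = False
        if s2_delay is None:
            while tissue.t < t_limit:
                tissue.step(dt_chunk, s1)
                vc = tissue.v[centre]
                if vc > UPSTROKE_THRESHOLD:
                    excited = True
                if excited and vc < tissue.cfg.v_iso - 15.0:
                    break
            else:
                return InitiationResult(False, 0, None,
                                        "S1 never reached centre")
        else:
            target = tissue.t + s2_delay
            while tissue.t < target:
                tissue.step(dt_chunk, s1)
        s2 = half_plane_stimulus(grid, s2_amplitude, s2_duration,
                                 t_on=tissue.t, axis=0,
                                 side="high" if mirror else "low")
        tissue.step(int(round(s2_duration / tissue.cfg.dt)) + 1, s2)
    tissue.step(int(round(settle / tissue.cfg.dt)))
    tips = tissue.detect_tips()
    n = len(tips)
    if n != 1:
        return InitiationResult(False, n, None,
                                f"{n} tips after settling (wanted 1)")
    return InitiationResult(True, 1, tips[0].chirality)


# -- regime probing ----------------------------------------------------


def probe_regime(alpha: float, nu: float, d_cells: float,
                 grid_shape: tuple, seed: int, duration: float = 400.0,
                 dt: float = 0.05, h: float = 0.025,
                 settle_time: float = 60.0,
                 params: CellParams | None = None) -> str:
    """Label a macroscopically homogeneous heterogeneous grid.

    Runs unstimulated from rest and classifies quiescent vs focal from
    post-settle upstrokes.
    """
    from .tissue_model import ALPHA_MAX
    if len(grid_shape) == 2:
        ny, nx = grid_shape
        grid = GridSpec(nx=nx, ny=ny, h=h)
    else:
        ny, nx, nz = grid_shape
        grid = GridSpec(nx=nx, ny=ny, nz=nz, h=h)
    params = params or CellParams()
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(grid.shape)
    alpha_cell = np.clip(alpha + nu * xi, 0.0, ALPHA_MAX)
    fields = uniform_fields(grid, d_cells, alpha_cell)
    cfg = SimConfig(dt=dt, duration=duration, settle_time=settle_time)
    tis = Tissue(grid, fields, params, cfg)
    tis.step(int(duration / dt))
    return wa.classify_regime(tis.upstroke_count, stimulated=False)


# -- end-to-end run ----------------------------------------------------


@dataclass
class RunResult:
    """Outcome of one protocol run."""

    frames: list = field(default_factory=list)   # (t, [TipPoint]) per frame
    tracks: list = field(default_factory=list)   # linked TipTrajectory
    events: list = field(default_factory=list)
    upstroke_count: np.ndarray | None = None
    final_state: dict | None = None
    config_hash: str = ""
    seed: int = 0

    def tip_table(self):
        import pandas as pd
        rows = []
        for tr in self.tracks:
            for t, x, y in zip(tr.t, tr.x, tr.y):
                rows.append({"t_ms": t, "x_cells": x, "y_cells": y,
                             "chirality": tr.chirality,
                             "track_id": tr.track_id})
        return pd.DataFrame(rows)


def _hash_config(obj) -> str:
    try:
        blob = json.dumps(obj, sort_keys=True, default=str)
    except TypeError:
        blob = repr(obj)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(tissue: Tissue, duration: float, i_ext=None,
        fields_at: Callable[[float], ParameterFields] | None = None,
        field_update_every: float = 10.0,
        detect: bool = True, on_frame=None) -> RunResult:
    """Execute a run with periodic online tip extraction.

    ``fields_at(t)`` supplies time-dependent parameter fields (the moving
    border zone); they are refreshed every ``field_update_every`` ms.
    Deterministic given the tissue state and arguments.
    """
    cfg = tissue.cfg
    stride = cfg.snapshot_stride
    n_steps = int(round(duration / cfg.dt))
    frames = []
    next_field_t = tissue.t
    for k in range(0, n_steps, stride):
        if fields_at is not None and tissue.t >= next_field_t:
            tissue.set_fields(fields_at(tissue.t))
            next_field_t += field_update_every
        tissue.step(min(stride, n_steps - k), i_ext)
        if detect and tissue.grid.ndim == 2:
            frames.append((tissue.t, tissue.detect_tips()))
        if on_frame is not None:
            on_frame(tissue)
    tracks = wa.link_tracks(frames) if detect and frames else []
    return RunResult(frames=frames, tracks=tracks,
                     upstroke_count=tissue.upstroke_count.copy(),
                     final_state=tissue.state_dict(),
                     config_hash=_hash_config(
                         {"dt": cfg.dt, "duration": duration,
                          "e": cfg.e_advect, "seed": cfg.seed}),
                     seed=cfg.seed)
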