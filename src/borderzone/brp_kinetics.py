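"""Beeler-Reuter-Pumir single-cell ionic model.

The cell model is the classic Beeler-Reuter ventricular kinetics with three
neonatal modifications: the fast-inward maximum conductance reduced to 60%
of standard (2.4 vs 4), the slow-inward conductance reduced to 50%
(0.045 vs 0.09), and the inward-rectifier current suppressed to a baseline
fraction ``k_k1_base`` and further scaled by ``(1 - alpha)``, where
``alpha`` in [0, 1) is the excitability parameter.  Raising ``alpha``
removes outward current, enhances excitability, and beyond a threshold
makes an isolated cell self-oscillatory (automatic).

All functions are vectorized: they accept scalars or numpy arrays of any
shape for the voltage/gate arguments.  Units are mV, ms, and the original
Beeler-Reuter current units (uA/cm^2 with unit membrane capacitance, so
currents read directly as mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy.optimize import brentq, fsolve

__all__ = [
    "GATE_NAMES",
    "N_VARS",
    "CellParams",
    "CellState",
    "ik1_scale",
    "gate_rates",
    "gate_steady_state",
    "currents",
    "cell_rhs",
    "find_rest_state",
    "step_cell",
    "simulate_cell",
    "count_upstrokes",
    "initial_state",
    "automaticity_threshold",
]

#: order of the six Hodgkin-Huxley gates in every array layout
GATE_NAMES = ("m", "h", "j", "d", "f", "x1")

#: number of dynamic variables per cell: V, Ca and six gates
N_VARS = 8

_ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class CellParams:
    """Parameters of one Beeler-Reuter-Pumir cell.

    Defaults encode the neonatal modifications; the remaining constants
    are the standard Beeler-Reuter values.
    """

    g_na: float = 2.4          # fast inward max conductance (60% of 4)
    g_nac: float = 0.003       # background sodium conductance
    e_na: float = 50.0         # sodium reversal potential, mV
    g_s: float = 0.045         # slow inward max conductance (50% of 0.09)
    k_k1_base: float = 0.5     # baseline neonatal suppression of i_K1
    alpha: float = 0.0         # excitability parameter, in [0, 1)
    c_m: float = 1.0           # membrane capacitance, uF/cm^2
    x1_speedup: float = 6.0    # rate scaling of the x1 gate (neonatal
                               # repolarization; leaves x1_inf unchanged)
    d_speedup: float = 4.0     # rate scaling of the d gate
    f_speedup: float = 4.0     # rate scaling of the f gate
    stim_amplitude: float = 30.0   # default stimulus, uA/cm^2
    stim_duration: float = 2.0     # default stimulus duration, ms

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if not (0.0 < self.k_k1_base <= 1.0):
            raise ValueError(
                f"k_k1_base must lie in (0, 1], got {self.k_k1_base}")

    def with_alpha(self, alpha: float) -> "CellParams":
        return replace(self, alpha=float(alpha))


@dataclass
class CellState:
    """Dynamic variables of one cell (or arrays of cells)."""

    v: _ArrayLike        # membrane voltage, mV
    ca: _ArrayLike       # intracellular calcium, model units (> 0)
    m: _ArrayLike
    h: _ArrayLike
    j: _ArrayLike
    d: _ArrayLike
    f: _ArrayLike
    x1: _ArrayLike

    def as_array(self) -> np.ndarray:
        """Stack into shape ``(8, ...)`` in the canonical variable order."""
        return np.stack([np.asarray(getattr(self, n), dtype=float)
                         for n in ("v", "ca") + GATE_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellState":
        names = ("v", "ca") + GATE_NAMES
        return cls(**{n: arr[i] for i, n in enumerate(names)})

    def copy(self) -> "CellState":
        return CellState.from_array(self.as_array().copy())

    def validate(self) -> None:
        v = np.asarray(self.v)
        if np.any(~np.isfinite(v)):
            raise FloatingPointError("non-finite voltage")
        if np.any(v < -120.0) or np.any(v > 80.0):
            raise ValueError("voltage outside [-120, 80] mV")
        if np.any(np.asarray(self.ca) <= 0.0):
            raise ValueError("calcium must stay positive")
        for n in GATE_NAMES:
            g = np.asarray(getattr(self, n))
            if np.any(g < 0.0) or np.any(g > 1.0):
                raise ValueError(f"gate {n} outside [0, 1]")


def ik1_scale(alpha: _ArrayLike) -> _ArrayLike:
    """Multiplier applied to the (already neonatally suppressed) i_K1.

    Linear convention: scale = 1 - alpha.  Monotonically non-increasing,
    equal to 1 at alpha = 0.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0.0) or np.any(a >= 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    out = 1.0 - a
    return float(out) if np.isscalar(alpha) else out


def _safe_ratio(num: np.ndarray, den: np.ndarray, limit: float) -> np.ndarray:
    """num/den with the removable singularity den == 0 replaced by limit."""
    small = np.abs(den) < 1e-12
    den = np.where(small, 1.0, den)
    return np.where(small, limit, num / den)


def gate_rates(v: _ArrayLike, params: "CellParams | None" = None) -> dict:
    """Beeler-Reuter opening/closing rates for the six gates at voltage v.

    Returns a dict ``{gate: (alpha_g, beta_g)}`` in 1/ms.  When ``params``
    carries kinetic speed-ups, the affected gate's rates are both scaled,
    shortening its time constant without moving its steady state.
    """
    v = np.asarray(v, dtype=float)
    e = np.exp

    vm47 = v + 47.0
    a_m = _safe_ratio(-vm47, e(-0.1 * vm47) - 1.0, 10.0)
    b_m = 40.0 * e(-0.056 * (v + 72.0))

    a_h = 0.126 * e(-0.25 * (v + 77.0))
    b_h = 1.7 / (e(-0.082 * (v + 22.5)) + 1.0)

    a_j = 0.055 * e(-0.25 * (v + 78.0)) / (e(-0.2 * (v + 78.0)) + 1.0)
    b_j = 0.3 / (e(-0.1 * (v + 32.0)) + 1.0)

    a_d = 0.095 * e(-0.01 * (v - 5.0)) / (e(-0.072 * (v - 5.0)) + 1.0)
    b_d = 0.07 * e(-0.017 * (v + 44.0)) / (e(0.05 * (v + 44.0)) + 1.0)

    a_f = 0.012 * e(-0.008 * (v + 28.0)) / (e(0.15 * (v + 28.0)) + 1.0)
    b_f = 0.0065 * e(-0.02 * (v + 30.0)) / (e(-0.2 * (v + 30.0)) + 1.0)

    a_x1 = 0.0005 * e(0.083 * (v + 50.0)) / (e(0.057 * (v + 50.0)) + 1.0)
    b_x1 = 0.0013 * e(-0.06 * (v + 20.0)) / (e(-0.04 * (v + 20.0)) + 1.0)

    if params is not None:
        sx, sd, sf = params.x1_speedup, params.d_speedup, params.f_speedup
        a_x1, b_x1 = sx * a_x1, sx * b_x1
        a_d, b_d = sd * a_d, sd * b_d
        a_f, b_f = sf * a_f, sf * b_f
    return {
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "j": (a_j, b_j),
        "d": (a_d, b_d),
        "f": (a_f, b_f),
        "x1": (a_x1, b_x1),
    }


def gate_steady_state(v: _ArrayLike,
                      params: "CellParams | None" = None) -> dict:
    """Voltage-dependent steady-state value g_inf = a/(a+b) per gate."""
    rates = gate_rates(v, params)
    return {g: a / (a + b) for g, (a, b) in rates.items()}


def currents(state: CellState, params: CellParams) -> dict:
    """The four membrane currents, in uA/cm^2 (outward positive)."""
    v = np.asarray(state.v, dtype=float)
    ca = np.asarray(state.ca, dtype=float)
    e = np.exp

    i_k1_full = 0.35 * (
        4.0 * (e(0.04 * (v + 85.0)) - 1.0)
        / (e(0.08 * (v + 53.0)) + e(0.04 * (v + 53.0)))
        + 0.2 * _safe_ratio(v + 23.0, 1.0 - e(-0.04 * (v + 23.0)), 25.0)
    )
    i_k1 = params.k_k1_base * ik1_scale(params.alpha) * i_k1_full

    i_x1 = state.x1 * 0.8 * (e(0.04 * (v + 77.0)) - 1.0) / e(0.04 * (v + 35.0))

    i_na = (params.g_na * state.m ** 3 * state.h * state.j
            + params.g_nac) * (v - params.e_na)

    e_s = -82.3 - 13.0287 * np.log(ca)
    i_s = params.g_s * state.d * state.f * (v - e_s)

    return {"i_k1": i_k1, "i_x1": i_x1, "i_na": i_na, "i_s": i_s}


def cell_rhs(state: CellState, params: CellParams,
             i_ext: _ArrayLike = 0.0) -> CellState:
    """Time derivatives of all eight variables.

    ``i_ext`` is an externally applied depolarizing current density
    (positive raises the voltage).
    """
    v = np.asarray(state.v, dtype=float)
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("non-finite voltage passed to cell_rhs")
    cur = currents(state, params)
    i_ion = cur["i_k1"] + cur["i_x1"] + cur["i_na"] + cur["i_s"]
    dv = (-i_ion + i_ext) / params.c_m
    dca = -1.0e-7 * cur["i_s"] + 0.07 * (1.0e-7 - np.asarray(state.ca))

    rates = gate_rates(v, params)
    dgates = {g: a * (1.0 - getattr(state, g)) - b * getattr(state, g)
              for g, (a, b) in rates.items()}
    return CellState(v=dv, ca=dca, **dgates)


def step_cell(state: CellState, dt: float, params: CellParams,
              i_ext: _ArrayLike = 0.0) -> CellState:
    """One integration step: Rush-Larsen for gates, forward Euler for V, Ca.

    The gate update ``g <- g_inf + (g - g_inf) exp(-dt (a+b))`` keeps every
    gate inside [0, 1] for arbitrarily large dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = np.asarray(state.v, dtype=float)
    cur = currents(state, params)
    i_ion = cur["i_k1"] + cur["i_x1"] + cur["i_na"] + cur["i_s"]
    v_new = v + dt * (-i_ion + i_ext) / params.c_m
    ca_new = np.asarray(state.ca) + dt * (
        -1.0e-7 * cur["i_s"] + 0.07 * (1.0e-7 - np.asarray(state.ca)))
    ca_new = np.maximum(ca_new, 1.0e-12)

    rates = gate_rates(v, params)
    new_gates = {}
    for g, (a, b) in rates.items():
        tau_inv = a + b
        g_inf = a / tau_inv
        new_gates[g] = g_inf + (getattr(state, g) - g_inf) * np.exp(
            -dt * tau_inv)
    if np.any(~np.isfinite(np.asarray(v_new))):
        raise FloatingPointError("NaN/Inf voltage produced in step_cell")
    return CellState(v=v_new, ca=ca_new, **new_gates)


def _rhs_vector(y: np.ndarray, params: CellParams) -> np.ndarray:
    # robust wrapper for root finders that may probe unphysical points
    y = np.asarray(y, dtype=float).copy()
    if not np.all(np.isfinite(y)):
        return np.full_like(y, 1e6)
    y[0] = np.clip(y[0], -200.0, 200.0)
    y[1] = max(y[1], 1e-12)
    state = CellState.from_array(y)
    return cell_rhs(state, params).as_array()


def initial_state(v: float = -84.0, ca: float = 1.8e-7) -> CellState:
    """A physiological starting point: gates at steady state for v."""
    ss = gate_steady_state(v)
    return CellState(v=v, ca=ca, **ss)


@dataclass
class RestStateResult:
    state: CellState | None
    residual: float
    stable: bool
    message: str = ""


def find_rest_state(params: CellParams, v_guess: float = -84.0,
                    tol: float = 1e-8) -> RestStateResult:
    """Locate the resting equilibrium of the cell by root finding.

    Returns the state with RHS norm below ``tol`` when a stable rest state
    exists.  When the cell is self-oscillatory (large alpha) the fixed
    point is either absent or linearly unstable; this is reported via
    ``stable=False`` rather than raising.
    """
    y0 = initial_state(v=v_guess).as_array()
    y, info, ier, msg = fsolve(_rhs_vector, y0, args=(params,),
                               full_output=True, xtol=1e-13)
    res = float(np.linalg.norm(_rhs_vector(y, params)))
    if ier != 1 or res > tol or y[1] <= 0:
        # relax toward the attractor with a stiff integrator, re-solve
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, yy: _rhs_vector(yy, params),
                        (0.0, 3000.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        y, info, ier, msg = fsolve(_rhs_vector, sol.y[:, -1],
                                   args=(params,), full_output=True,
                                   xtol=1e-13)
        res = float(np.linalg.norm(_rhs_vector(y, params)))
    if ier != 1 or res > tol or y[1] <= 0:
        return RestStateResult(None, res, False,
                               f"root finding failed: {msg}")
    state = CellState.from_array(y)

    # linear stability of the fixed point via finite-difference Jacobian
    n = N_VARS
    jac = np.empty((n, n))
    f0 = _rhs_vector(y, params)
    for k in range(n):
        dy = np.zeros(n)
        dy[k] = max(1e-7, 1e-7 * abs(y[k]))
        jac[:, k] = (_rhs_vector(y + dy, params) - f0) / dy[k]
    eigs = np.linalg.eigvals(jac)
    stable = bool(np.max(eigs.real) < 1e-9)
    return RestStateResult(state, res, stable,
                           "" if stable else "fixed point linearly unstable")


def simulate_cell(params: CellParams, duration: float, dt: float = 0.02,
                  state: CellState | None = None,
                  stim_times: tuple = (),
                  record_stride: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single cell, applying the params' stimulus at stim_times.

    Returns ``(t, V)`` sampled every ``record_stride`` steps.
    """
    if state is None:
        rest = find_rest_state(params)
        state = rest.state if rest.state is not None else initial_state()
    n_steps = int(round(duration / dt))
    ts, vs = [], []
    stim_times = np.asarray(sorted(stim_times), dtype=float)
    for i in range(n_steps):
        t = i * dt
        i_ext = 0.0
        if stim_times.size:
            active = (t >= stim_times) & (t < stim_times + params.stim_duration)
            if np.any(active):
                i_ext = params.stim_amplitude
        state = step_cell(state, dt, params, i_ext)
        if i % record_stride == 0:
            ts.append(t + dt)
            vs.append(float(state.v))
    return np.asarray(ts), np.asarray(vs)


def count_upstrokes(v: np.ndarray, threshold: float = -30.0) -> int:
    """Number of upward threshold crossings in a voltage trace."""
    above = v >= threshold
    return int(np.sum(~above[:-1] & above[1:]))


def automaticity_threshold(params: CellParams, lo: float = 0.0,
                           hi: float = 0.999, tol: float = 1e-3) -> float:
    """Critical alpha above which the isolated cell has no stable rest state.

    Bisection on the stability flag of :func:`find_rest_state`.
    """
    def unstable(a: float) -> bool:
        return not find_rest_state(params.with_alpha(a)).stable

    if unstable(lo):
        return lo
    if not unstable(hi):
        return hi
    return brentq(lambda a: 1.0 if unstable(a) else -1.0, lo, hi, xtol=tol)
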