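"""Asymptotic motion model of a spiral centre near a disk inhomogeneity.

The centre R (complex, origin at the disk centre) obeys

    dR/dt = F_grad - delta_alpha * (F_r(r) + i F_theta(r)) * R / r,

with r = |R|: a constant dragging force plus the distance-resolved
interaction curve, using the conventions of
:class:`~borderzone.force_estimation.ForceCurve` (F_r > 0 toward the
centre, F_theta > 0 clockwise).  Equilibria exist where the interaction
magnitude balances the drag; the polar-coordinate linearization gives
two closed-form stability conditions,

    d/dr [F_r^2 + F_theta^2] > 0   and   d/dr [r * delta_alpha * F_r] > 0,

which are evaluated from the interpolated curve and cross-checked
against the eigenvalues of the numerical Jacobian of the planar system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "DriftModel",
    "Equilibrium",
    "drift_rhs",
    "find_equilibria",
    "tear_off_threshold",
    "assess_stability",
    "integrate_drift",
    "superpose",
]


@dataclass
class DriftModel:
    """Constant gradient force plus a disk-interaction force curve."""

    f_grad: complex                  # dragging force, cells/ms
    delta_alpha: float               # contrast of the inhomogeneity
    d: np.ndarray                    # sampled distances (cells), increasing
    f_r: np.ndarray                  # per-unit-contrast radial force
    f_theta: np.ndarray              # per-unit-contrast azimuthal force
    convention: str = ("F_r>0 toward centre; F_theta>0 clockwise; "
                       "origin at the inhomogeneity centre")

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.f_r = np.asarray(self.f_r, dtype=float)
        self.f_theta = np.asarray(self.f_theta, dtype=float)
        if self.d.ndim != 1 or len(self.d) < 2:
            raise ValueError("need at least two curve samples")
        if np.any(np.diff(self.d) <= 0):
            raise ValueError("curve distances must be increasing")
        self._fr = PchipInterpolator(self.d, self.f_r, extrapolate=False)
        self._ft = PchipInterpolator(self.d, self.f_theta,
                                     extrapolate=False)

    @classmethod
    def from_force_curve(cls, curve, f_grad: complex,
                         delta_alpha: float | None = None) -> "DriftModel":
        return cls(f_grad=complex(f_grad),
                   delta_alpha=(curve.delta_alpha if delta_alpha is None
                                else float(delta_alpha)),
                   d=curve.d, f_r=curve.f_r, f_theta=curve.f_theta)

    @property
    def hg(self) -> float:
        """Magnitude of the dragging force."""
        return abs(self.f_grad)

    @property
    def gamma(self) -> float:
        """Direction of the dragging force, rad."""
        return math.atan2(self.f_grad.imag, self.f_grad.real)

    def interaction(self, r) -> tuple:
        """(F_r, F_theta) at radius r: clamped below the first sample,
        zero beyond the last."""
        r = np.asarray(r, dtype=float)
        rc = np.clip(r, self.d[0], self.d[-1])
        fr = np.where(r > self.d[-1], 0.0, self._fr(rc))
        ft = np.where(r > self.d[-1], 0.0, self._ft(rc))
        return fr, ft

    def magnitude2(self, r) -> np.ndarray:
        fr, ft = self.interaction(r)
        return fr * fr + ft * ft


def drift_rhs(R: complex, model: DriftModel) -> complex:
    """Centre velocity at position R (origin at the disk centre)."""
    r = abs(R)
    if r == 0.0:
        raise ZeroDivisionError("drift velocity is singular at the origin")
    fr, ft = model.interaction(r)
    return model.f_grad - model.delta_alpha * complex(float(fr),
                                                      float(ft)) * R / r


@dataclass
class Equilibrium:
    radius: float
    angle: float
    position: complex
    stable: bool | None = None       # None until classified
    marginal: bool = False
    eigenvalues: np.ndarray | None = None
    conditions: tuple | None = None  # the two closed-form conditions
    residual: float = 0.0


def tear_off_threshold(model: DriftModel, n_dense: int = 2001) -> float:
    """Critical drag magnitude: max over r of the interaction magnitude.

    Above this the dragging force tears the spiral off regardless of
    position.
    """
    r = np.linspace(model.d[0], model.d[-1], n_dense)
    return float(abs(model.delta_alpha)
                 * np.sqrt(np.max(model.magnitude2(r))))


def find_equilibria(model: DriftModel, n_scan: int = 2001,
                    tol: float = 1e-12) -> list[Equilibrium]:
    """All equilibria of the drift equation by radial scan + bisection.

    Radii solve delta_alpha^2 (F_r^2 + F_theta^2)(r) = hg^2; the angle
    follows from the force balance.  Every returned equilibrium is
    verified to have |dR/dt| below 1e-10 of the force scale.
    """
    hg = model.hg
    da = model.delta_alpha
    scale = max(hg, tear_off_threshold(model), 1e-30)

    def g(r: float) -> float:
        return da * da * float(model.magnitude2(r)) - hg * hg

    rs = np.linspace(model.d[0], model.d[-1], n_scan)
    gs = np.array([g(r) for r in rs])
    roots = []
    for i in range(len(rs) - 1):
        if gs[i] == 0.0:
            roots.append(rs[i])
        elif gs[i] * gs[i + 1] < 0:
            roots.append(brentq(g, rs[i], rs[i + 1], xtol=tol))
    if gs[-1] == 0.0:
        roots.append(rs[-1])

    out = []
    for r_star in roots:
        fr, ft = model.interaction(r_star)
        denom = da * complex(float(fr), float(ft))
        if abs(denom) == 0.0:
            if hg > 0:
                continue
            unit = 1.0 + 0.0j
        else:
            unit = model.f_grad / denom if hg > 0 else 1.0 + 0.0j
            nm = abs(unit)
            if nm == 0.0:
                continue
            unit = unit / nm
        pos = r_star * unit
        res = abs(drift_rhs(pos, model))
        if res <= 1e-10 * scale + 1e-13:
            out.append(Equilibrium(radius=float(r_star),
                                   angle=float(np.angle(pos)),
                                   position=pos, residual=float(res)))
    return out


def _condition_derivatives(model: DriftModel, r: float,
                           rel_step: float = 1e-5) -> tuple:
    """Finite-difference d/dr of the two stability functions at r."""
    dr = max(rel_step * (model.d[-1] - model.d[0]), 1e-9)
    lo, hi = r - dr, r + dr
    if lo < model.d[0] or hi > model.d[-1]:
        raise ValueError("equilibrium too close to the curve edge for "
                         "finite differences")
    m2 = (float(model.magnitude2(hi)) - float(model.magnitude2(lo)))
    fr_lo, _ = model.interaction(lo)
    fr_hi, _ = model.interaction(hi)
    rf = (hi * model.delta_alpha * float(fr_hi)
          - lo * model.delta_alpha * float(fr_lo))
    return m2 / (2 * dr), rf / (2 * dr)


def _planar_jacobian(model: DriftModel, pos: complex,
                     rel_step: float = 1e-7) -> np.ndarray:
    """Numerical Jacobian of the planar (x, y) drift system."""
    step = max(rel_step * abs(pos), 1e-9)
    jac = np.empty((2, 2))
    for k, dz in enumerate((step, 1j * step)):
        vp = drift_rhs(pos + dz, model)
        vm = drift_rhs(pos - dz, model)
        jac[0, k] = (vp.real - vm.real) / (2 * step)
        jac[1, k] = (vp.imag - vm.imag) / (2 * step)
    return jac


def assess_stability(model: DriftModel, eq: Equilibrium,
                     marginal_tol: float = 1e-8) -> Equilibrium:
    """Classify an equilibrium by the closed-form conditions + Jacobian.

    Both routes must agree (unless marginal); disagreement raises.
    """
    res = abs(drift_rhs(eq.position, model))
    scale = max(model.hg, tear_off_threshold(model), 1e-30)
    if res > 1e-8 * scale + 1e-12:
        raise ValueError("assess_stability called on a non-equilibrium")

    dm2, drf = _condition_derivatives(model, eq.radius)
    cond = (bool(dm2 > 0.0), bool(drf > 0.0))
    analytic_stable = cond[0] and cond[1]

    jac = _planar_jacobian(model, eq.position)
    eigs = np.linalg.eigvals(jac)
    max_re = float(np.max(eigs.real))
    eig_scale = float(max(np.max(np.abs(eigs)), 1e-30))
    marginal = bool(abs(max_re) < marginal_tol * eig_scale)
    jac_stable = bool(max_re < 0.0)

    if not marginal and analytic_stable != jac_stable:
        raise RuntimeError(
            f"stability classifications disagree at r={eq.radius:.4g}: "
            f"conditions={cond}, max Re eig={max_re:.3g}")
    eq.stable = None if marginal else jac_stable
    eq.marginal = marginal
    eq.eigenvalues = eigs
    eq.conditions = cond
    return eq


@dataclass
class DriftTrajectory:
    t: np.ndarray
    z: np.ndarray
    events: list = field(default_factory=list)
    escaped: bool = False


def integrate_drift(model: DriftModel, r0: complex, t_final: float,
                    rtol: float = 1e-8, atol: float = 1e-10,
                    max_radius: float | None = None) -> DriftTrajectory:
    """Integrate the centre motion adaptively from R(0) = r0.

    Records an escape event when the centre leaves the sampled curve
    range (beyond which the interaction is zero and drift is unbounded).
    """
    r_max = max_radius if max_radius is not None else 4.0 * model.d[-1]

    def rhs(t, y):
        v = drift_rhs(complex(y[0], y[1]), model)
        return [v.real, v.imag]

    def escape(t, y):
        return math.hypot(y[0], y[1]) - r_max
    escape.terminal = True
    escape.direction = 1.0

    sol = solve_ivp(rhs, (0.0, t_final), [r0.real, r0.imag],
                    rtol=rtol, atol=atol, dense_output=True,
                    events=[escape], max_step=t_final / 50.0)
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"drift integration failed: {sol.message}")
    z = sol.y[0] + 1j * sol.y[1]
    events = []
    escaped = sol.status == 1
    if escaped:
        events.append(("escape", float(sol.t[-1])))
    return DriftTrajectory(t=sol.t, z=z, events=events, escaped=escaped)


def superpose(forces) -> complex:
    """Net complex force from (magnitude, specific-force) pairs.

    Entries may be ``(magnitude, SpecificForce)`` or
    ``(magnitude, complex)``.  Specific forces measured for opposite
    chiralities do not share conventions and cannot be summed.
    """
    total = 0.0 + 0.0j
    chis = set()
    for mag, f in forces:
        val = getattr(f, "value", f)
        chi = getattr(f, "chirality", None)
        if chi is not None:
            chis.add(chi)
        total += mag * complex(val)
    if len(chis) > 1:
        raise ValueError("mixed conventions: forces estimated for "
                         "opposite chiralities cannot be superposed")
    return total
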