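"""Phase-singularity analysis of voltage / inactivation-gate fields.

A 2D spiral tip is the intersection of two isolines, V = V_iso and
f = f_iso, located with sub-cell resolution by solving the bilinear
interpolants inside each grid square.  The chirality is the sign of the
cross product grad V x grad f at the intersection.  In 3D the same
construction is applied to every voxel face; face crossings are linked
through voxels into filament polylines.

Also here: tip-track linking, rotation-period and drift-velocity
estimation from sliding period-averaged tip positions, activity-regime
classification, critical-heterogeneity transition curves, and persistent
spiral counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TipPoint",
    "TipTrajectory",
    "Filament",
    "detect_tips",
    "extract_filaments",
    "link_tracks",
    "drift_velocity",
    "classify_regime",
    "transition_curve",
    "count_spirals",
]


@dataclass(frozen=True)
class TipPoint:
    """One phase singularity at one instant (positions in cell units)."""

    x: float
    y: float
    chirality: int
    t: float = 0.0
    z: float = 0.0


@dataclass
class TipTrajectory:
    """Ordered tip positions of one linked track."""

    t: np.ndarray            # ms, strictly increasing
    x: np.ndarray            # cell units
    y: np.ndarray
    chirality: int = 0
    track_id: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def z(self) -> np.ndarray:
        """Positions as complex numbers x + i y."""
        return self.x + 1j * self.y

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class Filament:
    """A 3D filament polyline (positions in cell units)."""

    points: np.ndarray       # (n, 3) array of (x, y, z)
    closed: bool = False

    @property
    def length(self) -> float:
        pts = self.points
        if self.closed and len(pts) > 1:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _square_crossings(a: np.ndarray, b: np.ndarray):
    """Isoline intersections of two bilinear fields, already offset to 0.

    Returns a list of ``(row, col, s, t, chirality)`` where ``s`` runs
    along columns and ``t`` along rows, both in [0, 1].
    """
    a00, a10 = a[:-1, :-1], a[:-1, 1:]
    a01, a11 = a[1:, :-1], a[1:, 1:]
    b00, b10 = b[:-1, :-1], b[:-1, 1:]
    b01, b11 = b[1:, :-1], b[1:, 1:]

    amin = np.minimum(np.minimum(a00, a10), np.minimum(a01, a11))
    amax = np.maximum(np.maximum(a00, a10), np.maximum(a01, a11))
    bmin = np.minimum(np.minimum(b00, b10), np.minimum(b01, b11))
    bmax = np.maximum(np.maximum(b00, b10), np.maximum(b01, b11))
    cand = (amin <= 0) & (amax >= 0) & (bmin <= 0) & (bmax >= 0)

    eps = 1e-9
    out = []
    for r, c in np.argwhere(cand):
        p0, p1 = a00[r, c], a10[r, c] - a00[r, c]
        p2 = a01[r, c] - a00[r, c]
        p3 = a11[r, c] - a10[r, c] - a01[r, c] + a00[r, c]
        q0, q1 = b00[r, c], b10[r, c] - b00[r, c]
        q2 = b01[r, c] - b00[r, c]
        q3 = b11[r, c] - b10[r, c] - b01[r, c] + b00[r, c]

        c2 = q1 * p3 - q3 * p1
        c1 = q0 * p3 + q1 * p2 - q2 * p1 - q3 * p0
        c0 = q0 * p2 - q2 * p0
        if abs(c2) < 1e-14 * max(1.0, abs(c1), abs(c0)):
            roots = [-c0 / c1] if abs(c1) > 1e-14 else []
        else:
            disc = c1 * c1 - 4.0 * c2 * c0
            if disc < 0:
                continue
            sq = math.sqrt(disc)
            roots = [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]
        for s in roots:
            if not (-eps <= s <= 1.0 + eps):
                continue
            den_a = p2 + p3 * s
            den_b = q2 + q3 * s
            if abs(den_a) >= abs(den_b):
                if abs(den_a) < 1e-14:
                    continue
                t = -(p0 + p1 * s) / den_a
            else:
                t = -(q0 + q1 * s) / den_b
            if not (-eps <= t <= 1.0 + eps):
                continue
            s_c, t_c = min(max(s, 0.0), 1.0), min(max(t, 0.0), 1.0)
            cross = ((p1 + p3 * t_c) * (q2 + q3 * s_c)
                     - (p2 + p3 * s_c) * (q1 + q3 * t_c))
            chi = 1 if cross > 0 else -1
            if not any(r == r2 and c == c2_ and abs(s_c - s2) < 1e-6
                       and abs(t_c - t2) < 1e-6
                       for r2, c2_, s2, t2, _ in out):
                out.append((r, c, s_c, t_c, chi))
    return out


def detect_tips(v: np.ndarray, f: np.ndarray, v_iso: float,
                f_iso: float, t: float = 0.0) -> list[TipPoint]:
    """Spiral tips as intersections of the V and f isolines.

    Fields are 2D arrays indexed ``[iy, ix]``; returned positions are in
    cell units with sub-cell resolution.
    """
    if v.shape != f.shape or v.ndim != 2:
        raise ValueError("v and f must be 2D arrays of equal shape")
    tips = []
    for r, c, s, tt, chi in _square_crossings(v - v_iso, f - f_iso):
        tips.append(TipPoint(x=c + s, y=r + tt, chirality=chi, t=t))
    return tips


def extract_filaments(v: np.ndarray, f: np.ndarray, v_iso: float,
                      f_iso: float) -> list[Filament]:
    """Scroll-wave filaments from 3D fields indexed ``[iy, ix, iz]``.

    Runs the 2D isoline-intersection detector on every voxel face and
    links the face crossings through shared voxels into polylines.
    Closed loops are flagged.
    """
    if v.shape != f.shape or v.ndim != 3:
        raise ValueError("v and f must be 3D arrays of equal shape")
    ny, nx, nz = v.shape
    a = v - v_iso
    b = f - f_iso

    nodes = []       # (x, y, z) positions in cell units
    voxel_map = {}   # voxel index -> list of node ids

    def add(pos, voxels):
        nid = len(nodes)
        nodes.append(pos)
        for vox in voxels:
            iy, ix, iz = vox
            if 0 <= iy < ny - 1 and 0 <= ix < nx - 1 and 0 <= iz < nz - 1:
                voxel_map.setdefault(vox, []).append(nid)

    # faces perpendicular to z: rows = iy (t), cols = ix (s)
    for k in range(nz):
        for r, c, s, t, _ in _square_crossings(a[:, :, k], b[:, :, k]):
            add((c + s, r + t, float(k)),
                [(r, c, k - 1), (r, c, k)])
    # faces perpendicular to y: rows = ix (t), cols = iz (s)
    for jy in range(ny):
        for r, c, s, t, _ in _square_crossings(a[jy, :, :], b[jy, :, :]):
            add((r + t, float(jy), c + s),
                [(jy - 1, r, c), (jy, r, c)])
    # faces perpendicular to x: rows = iy (t), cols = iz (s)
    for jx in range(nx):
        for r, c, s, t, _ in _square_crossings(a[:, jx, :], b[:, jx, :]):
            add((float(jx), r + t, c + s),
                [(r, jx - 1, c), (r, jx, c)])

    # connect crossings that share a voxel
    adjacency: dict[int, set] = {i: set() for i in range(len(nodes))}
    for ids in voxel_map.values():
        if len(ids) < 2:
            continue
        remaining = list(ids)
        # pair nearest crossings within the voxel
        while len(remaining) >= 2:
            i0 = remaining.pop(0)
            p0 = np.asarray(nodes[i0])
            dists = [np.linalg.norm(np.asarray(nodes[i1]) - p0)
                     for i1 in remaining]
            i1 = remaining.pop(int(np.argmin(dists)))
            adjacency[i0].add(i1)
            adjacency[i1].add(i0)

    # walk the degree <= 2 graph into polylines
    filaments = []
    visited = set()
    ends = [i for i in adjacency if len(adjacency[i]) <= 1]
    order = ends + [i for i in adjacency if len(adjacency[i]) > 1]
    for start in order:
        if start in visited or not adjacency[start]:
            continue
        path = [start]
        visited.add(start)
        cur = start
        closed = False
        while True:
            nxt = [n for n in adjacency[cur] if n not in visited]
            if not nxt:
                closed = start in adjacency[cur] and len(path) > 2
                break
            cur = nxt[0]
            visited.add(cur)
            path.append(cur)
        if len(path) >= 2:
            pts = np.asarray([nodes[i] for i in path], dtype=float)
            filaments.append(Filament(points=pts, closed=closed))
    return filaments


def link_tracks(frames: list[tuple[float, list[TipPoint]]],
                max_jump: float = 2.0,
                max_gap: int = 10) -> list[TipTrajectory]:
    """Link per-frame tip detections into trajectories.

    Nearest-neighbour association gated at ``max_jump`` cells per frame;
    same-chirality matches only; tracks missing more than ``max_gap``
    consecutive frames are terminated.
    """
    active: list[dict] = []
    done: list[dict] = []
    for t, tips in frames:
        used = set()
        for tr in active:
            best, best_d = None, max_jump * (tr["miss"] + 1)
            for i, tip in enumerate(tips):
                if i in used or tip.chirality != tr["chi"]:
                    continue
                d = math.hypot(tip.x - tr["x"][-1], tip.y - tr["y"][-1])
                if d < best_d:
                    best, best_d = i, d
            if best is not None:
                tip = tips[best]
                used.add(best)
                tr["t"].append(t)
                tr["x"].append(tip.x)
                tr["y"].append(tip.y)
                tr["miss"] = 0
            else:
                tr["miss"] += 1
        still = []
        for tr in active:
            (done if tr["miss"] > max_gap else still).append(tr)
        active = [tr for tr in still if tr["miss"] <= max_gap]
        for i, tip in enumerate(tips):
            if i not in used:
                active.append({"t": [t], "x": [tip.x], "y": [tip.y],
                               "chi": tip.chirality, "miss": 0})
    done.extend(active)
    tracks = []
    for k, tr in enumerate(d for d in done if len(d["t"]) >= 2):
        tracks.append(TipTrajectory(
            t=np.asarray(tr["t"]), x=np.asarray(tr["x"]),
            y=np.asarray(tr["y"]), chirality=tr["chi"], track_id=k))
    return tracks


@dataclass
class DriftEstimate:
    velocity: complex        # cells/ms (or mm/ms if positions were mm)
    uncertainty: float       # 1-sigma on |velocity|
    period: float            # rotation period, ms
    centre: np.ndarray       # sliding period-averaged centre series
    centre_t: np.ndarray


def estimate_period(traj: TipTrajectory, min_period: float = 20.0) -> float:
    """Rotation period from the autocorrelation of the detrended orbit.

    The tip orbit, linearly detrended, is close to A exp(2 pi i t / T);
    the real part of its complex autocorrelation peaks at lag T.  The
    peak is refined parabolically.  Requires a trajectory covering at
    least ~2 rotations.
    """
    t, z = traj.t, traj.z
    if len(t) < 8:
        raise ValueError("trajectory too short for period estimation")
    dt = float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1], dt)
    zu = np.interp(tu, t, z.real) + 1j * np.interp(tu, t, z.imag)
    coef = np.polyfit(tu, zu, 1)
    res = zu - np.polyval(coef, tu)
    n = len(res)
    k_min = max(2, int(min_period / dt))
    k_max = n * 2 // 3
    if k_max <= k_min + 2:
        raise ValueError("trajectory too short for period estimation")
    # normalized overlap correlation at each lag
    corr = np.empty(k_max - k_min)
    for i, k in enumerate(range(k_min, k_max)):
        a, b = res[:-k], res[k:]
        denom = math.sqrt(float(np.sum(np.abs(a) ** 2)
                                * np.sum(np.abs(b) ** 2))) + 1e-30
        corr[i] = float(np.real(np.sum(a * np.conj(b)))) / denom
    i_pk = int(np.argmax(corr))
    if corr[i_pk] < 0.2:
        raise ValueError("no clear rotation periodicity in trajectory")
    # parabolic refinement of the peak lag
    if 0 < i_pk < len(corr) - 1:
        y0, y1, y2 = corr[i_pk - 1], corr[i_pk], corr[i_pk + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
    else:
        shift = 0.0
    return (k_min + i_pk + shift) * dt


def drift_velocity(traj: TipTrajectory,
                   period: float | None = None) -> DriftEstimate:
    """Drift velocity from sliding one-period averages of the tip path.

    The centre series is the boxcar average of the tip position over one
    rotation period; its linear-regression slope is the drift velocity,
    with the 1-sigma uncertainty from the regression residuals.
    Requires a trajectory spanning at least ~3 rotation periods (5 for a
    trustworthy uncertainty).
    """
    if period is None:
        period = estimate_period(traj)
    if traj.duration < 3 * period:
        raise ValueError(
            f"trajectory spans {traj.duration:.1f} ms < 3 periods "
            f"({period:.1f} ms each)")
    t, z = traj.t, traj.z
    dt = float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1], dt)
    zu = np.interp(tu, t, z.real) + 1j * np.interp(tu, t, z.imag)
    w = max(2, int(round(period / dt)))
    kern = np.ones(w) / w
    centre = np.convolve(zu, kern, mode="valid")
    tc = tu[w - 1:] - (w - 1) * dt / 2.0
    if len(centre) < 4:
        raise ValueError("too few centre samples after period averaging")
    coef, cov = np.polyfit(tc, centre, 1, cov=True)
    v = complex(coef[0])
    # residual-based uncertainty; period-averaged samples are strongly
    # correlated, so inflate by sqrt of samples per period
    resid = centre - np.polyval(coef, tc)
    sig = math.sqrt(abs(cov[0, 0])) * math.sqrt(max(1.0, w))
    sig = max(sig, float(np.std(np.abs(resid))) / max(tc[-1] - tc[0], 1e-9))
    return DriftEstimate(velocity=v, uncertainty=float(sig),
                         period=float(period), centre=centre, centre_t=tc)


def classify_regime(upstroke_count: np.ndarray, stimulated: bool) -> str:
    """Label network activity after the settling window.

    ``upstroke_count`` counts post-settle upstrokes per cell.  Focal
    activity means a self-depolarizing cell whose activity reached at
    least one neighbour; stimulated runs with activity are
    propagating-only.
    """
    fired = upstroke_count > 0
    if not np.any(fired):
        return "quiescent"
    if stimulated:
        return "propagating-only"
    spread = False
    for axis in range(fired.ndim):
        lo = [slice(None)] * fired.ndim
        hi = [slice(None)] * fired.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        if np.any(fired[tuple(lo)] & fired[tuple(hi)]):
            spread = True
            break
    return "focal" if spread else "quiescent"


def transition_curve(alpha_list, nu_bracket, d_cells: float,
                     grid_shape: tuple, trials: int = 3, seed: int = 0,
                     n_iter: int = 6, duration: float = 400.0,
                     dt: float = 0.05, h: float = 0.025):
    """Critical heterogeneity intensity nu_c(alpha) by bisection.

    For each alpha, runs short unstimulated simulations of a macroscopically
    homogeneous grid at candidate nu, classifies focal vs quiescent by
    majority vote over ``trials`` heterogeneity realizations, and bisects
    the bracket.  ``d_cells`` is diffusivity in cell units (D / h^2, 1/ms);
    ``grid_shape`` is (ny, nx) or (ny, nx, nz).

    Returns a list of dicts with nu_c and the final bracket per alpha.
    """
    from .simulator import probe_regime   # local import: avoids cycle

    if trials % 2 == 0:
        trials += 1
    nu_lo0, nu_hi0 = nu_bracket
    results = []
    rng = np.random.default_rng(seed)
    for alpha in alpha_list:
        seeds = rng.integers(0, 2 ** 31, size=trials * (n_iter + 2) * 2)
        si = iter(seeds.tolist())

        def vote(nu: float) -> bool:
            focal = 0
            for _ in range(trials):
                lab = probe_regime(alpha, nu, d_cells, grid_shape,
                                   seed=next(si), duration=duration,
                                   dt=dt, h=h)
                focal += lab == "focal"
            return focal > trials // 2

        lo, hi = nu_lo0, nu_hi0
        if vote(lo) or not vote(hi):
            raise ValueError(
                f"nu bracket ({lo}, {hi}) does not straddle the transition "
                f"at alpha={alpha}")
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            if vote(mid):
                hi = mid
            else:
                lo = mid
        results.append({"alpha": float(alpha),
                        "nu_c": 0.5 * (lo + hi),
                        "nu_lo": lo, "nu_hi": hi,
                        "trials": trials})
    return results


def count_spirals(tracks: list[TipTrajectory], t_after: float,
                  period: float, min_periods: float = 3.0) -> int:
    """Number of persistent spiral tracks alive after ``t_after``.

    A track counts if it survives at least ``min_periods`` rotation
    periods beyond ``t_after``.
    """
    n = 0
    for tr in tracks:
        if tr.t[-1] >= t_after + min_periods * period and \
                tr.t[-1] - max(tr.t[0], t_after) >= min_periods * period:
            n += 1
    return n
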