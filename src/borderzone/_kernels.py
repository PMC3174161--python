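"""Compiled inner loop of the tissue stepper (numba, optional).

One kernel covers 2D and 3D: 2D sheets are passed as (ny, nx, 1).  The
voltage-dependent factors arrive as a dense table with one row per
voltage sample (14 columns: per-gate g_inf and exp factor, i_K1, x1
coefficient) and are linearly interpolated per cell.  Falls back to the
pure-numpy path in :mod:`simulator` when numba is unavailable.
"""

from __future__ import annotations

import math

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is pre-installed normally
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=True)
def step_kernel(v, ca, m, h, jg, dg, fg, x1, k1s, gy, gx, gz, table,
                v_min, inv_dv, dt, e_over_2h, i_ext, has_stim,
                g_na, g_nac, e_na, g_s, inv_cm, v_out):
    ny, nx, nz = v.shape
    nrow = table.shape[0]
    for iy in range(ny):
        for ix in range(nx):
            for iz in range(nz):
                vi = v[iy, ix, iz]
                # table interpolation
                ti = (vi - v_min) * inv_dv
                if ti < 0.0:
                    ti = 0.0
                elif ti > nrow - 1.001:
                    ti = nrow - 1.001
                i0 = int(ti)
                w = ti - i0

                # coupling (no-flux boundaries)
                c = 0.0
                if iy > 0:
                    c += gy[iy - 1, ix, iz] * (v[iy - 1, ix, iz] - vi)
                if iy < ny - 1:
                    c += gy[iy, ix, iz] * (v[iy + 1, ix, iz] - vi)
                if ix > 0:
                    c += gx[iy, ix - 1, iz] * (v[iy, ix - 1, iz] - vi)
                if ix < nx - 1:
                    c += gx[iy, ix, iz] * (v[iy, ix + 1, iz] - vi)
                if nz > 1:
                    if iz > 0:
                        c += gz[iy, ix, iz - 1] * (v[iy, ix, iz - 1] - vi)
                    if iz < nz - 1:
                        c += gz[iy, ix, iz] * (v[iy, ix, iz + 1] - vi)

                # advection E dV/dx, central differences, one-sided at edges
                if e_over_2h != 0.0:
                    if 0 < ix < nx - 1:
                        c += e_over_2h * (v[iy, ix + 1, iz]
                                          - v[iy, ix - 1, iz])
                    elif ix == 0:
                        c += 2.0 * e_over_2h * (v[iy, 1, iz] - vi)
                    else:
                        c += 2.0 * e_over_2h * (vi - v[iy, nx - 2, iz])

                # currents
                ik1 = k1s[iy, ix, iz] * (
                    table[i0, 12] + (table[i0 + 1, 12] - table[i0, 12]) * w)
                cx1 = table[i0, 13] + (table[i0 + 1, 13] - table[i0, 13]) * w
                ix1 = x1[iy, ix, iz] * cx1
                mm = m[iy, ix, iz]
                ina = (g_na * mm * mm * mm * h[iy, ix, iz] * jg[iy, ix, iz]
                       + g_nac) * (vi - e_na)
                cai = ca[iy, ix, iz]
                es = -82.3 - 13.0287 * math.log(cai)
                i_s = g_s * dg[iy, ix, iz] * fg[iy, ix, iz] * (vi - es)

                dv = -(ik1 + ix1 + ina + i_s) * inv_cm + c
                if has_stim:
                    dv += i_ext[iy, ix, iz]
                v_out[iy, ix, iz] = vi + dt * dv

                cai = cai + dt * (-1.0e-7 * i_s + 0.07 * (1.0e-7 - cai))
                ca[iy, ix, iz] = cai if cai > 1e-12 else 1e-12

                # Rush-Larsen gate updates
                gi = table[i0, 0] + (table[i0 + 1, 0] - table[i0, 0]) * w
                ef = table[i0, 1] + (table[i0 + 1, 1] - table[i0, 1]) * w
                m[iy, ix, iz] = gi + (mm - gi) * ef
                gi = table[i0, 2] + (table[i0 + 1, 2] - table[i0, 2]) * w
                ef = table[i0, 3] + (table[i0 + 1, 3] - table[i0, 3]) * w
                h[iy, ix, iz] = gi + (h[iy, ix, iz] - gi) * ef
                gi = table[i0, 4] + (table[i0 + 1, 4] - table[i0, 4]) * w
                ef = table[i0, 5] + (table[i0 + 1, 5] - table[i0, 5]) * w
                jg[iy, ix, iz] = gi + (jg[iy, ix, iz] - gi) * ef
                gi = table[i0, 6] + (table[i0 + 1, 6] - table[i0, 6]) * w
                ef = table[i0, 7] + (table[i0 + 1, 7] - table[i0, 7]) * w
                dg[iy, ix, iz] = gi + (dg[iy, ix, iz] - gi) * ef
                gi = table[i0, 8] + (table[i0 + 1, 8] - table[i0, 8]) * w
                ef = table[i0, 9] + (table[i0 + 1, 9] - table[i0, 9]) * w
                fg[iy, ix, iz] = gi + (fg[iy, ix, iz] - gi) * ef
                gi = table[i0, 10] + (table[i0 + 1, 10] - table[i0, 10]) * w
                ef = table[i0, 11] + (table[i0 + 1, 11] - table[i0, 11]) * w
                x1[iy, ix, iz] = gi + (x1[iy, ix, iz] - gi) * ef
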