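"""Fused numba kernel for the field right-hand side.

Numerically identical (to rounding) to the pure-numpy reference in
:mod:`cellstrand.dynamics`; the test suite checks the two paths against
each other.  Falls back silently when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rhs_kernel(
    phi,
    out,
    boxes,  # (n, 4) int64: y0, y1, x0, x1 (half-open; x range may wrap)
    wall_excl,  # 2 * g_wall * wall^2
    wadh_x,  # kappa * f(grad wall)_x
    wadh_y,
    px,
    py,
    h,
    periodic_x,
    alpha,
    K,
    lam,
    a0,
    g,
    gamma,
    omega,
    eps,
):  # pragma: no cover - exercised through step_fields
    n, ny, nx = phi.shape
    h2 = 2.0 * h
    hh = h * h

    out[:] = 0.0
    sumsq = np.zeros((ny, nx))
    areas = np.zeros(n)
    for c in range(n):
        s = 0.0
        for iy in range(boxes[c, 0], boxes[c, 1]):
            for jx in range(boxes[c, 2], boxes[c, 3]):
                ix = jx % nx
                v = phi[c, iy, ix]
                v2 = v * v
                sumsq[iy, ix] += v2
                s += v2
        areas[c] = s * hh

    gx = np.empty((n, ny, nx))
    gy = np.empty((n, ny, nx))
    sfx = np.zeros((ny, nx))
    sfy = np.zeros((ny, nx))
    fx = np.empty((n, ny, nx))
    fy = np.empty((n, ny, nx))
    for c in range(n):
        for iy in range(boxes[c, 0], boxes[c, 1]):
            for jx in range(boxes[c, 2], boxes[c, 3]):
                ix = jx % nx
                # x derivative
                if periodic_x:
                    xp = ix + 1 if ix + 1 < nx else 0
                    xm = ix - 1 if ix - 1 >= 0 else nx - 1
                    dx = (phi[c, iy, xp] - phi[c, iy, xm]) / h2
                else:
                    if ix == 0:
                        dx = (-3.0 * phi[c, iy, 0] + 4.0 * phi[c, iy, 1] - phi[c, iy, 2]) / h2
                    elif ix == nx - 1:
                        dx = (3.0 * phi[c, iy, nx - 1] - 4.0 * phi[c, iy, nx - 2] + phi[c, iy, nx - 3]) / h2
                    else:
                        dx = (phi[c, iy, ix + 1] - phi[c, iy, ix - 1]) / h2
                # y derivative (walled)
                if iy == 0:
                    dy = (-3.0 * phi[c, 0, ix] + 4.0 * phi[c, 1, ix] - phi[c, 2, ix]) / h2
                elif iy == ny - 1:
                    dy = (3.0 * phi[c, ny - 1, ix] - 4.0 * phi[c, ny - 2, ix] + phi[c, ny - 3, ix]) / h2
                else:
                    dy = (phi[c, iy + 1, ix] - phi[c, iy - 1, ix]) / h2
                gx[c, iy, ix] = dx
                gy[c, iy, ix] = dy
                denom = 1.0 + eps * (dx * dx + dy * dy)
                fxi = dx / denom
                fyi = dy / denom
                fx[c, iy, ix] = fxi
                fy[c, iy, ix] = fyi
                sfx[iy, ix] += fxi
                sfy[iy, ix] += fyi

    for c in range(n):
        adef = 1.0 - areas[c] / a0
        carea = -4.0 * lam / a0 * adef
        for iy in range(boxes[c, 0], boxes[c, 1]):
            for jx in range(boxes[c, 2], boxes[c, 3]):
                ix = jx % nx
                v = phi[c, iy, ix]
                # laplacian (mirror ghost at walled edges, wrap on periodic x)
                if periodic_x:
                    xp = ix + 1 if ix + 1 < nx else 0
                    xm = ix - 1 if ix - 1 >= 0 else nx - 1
                    lap = phi[c, iy, xp] + phi[c, iy, xm]
                else:
                    xp = ix + 1 if ix + 1 < nx else nx - 2
                    xm = ix - 1 if ix - 1 >= 0 else 1
                    lap = phi[c, iy, xp] + phi[c, iy, xm]
                yp = iy + 1 if iy + 1 < ny else ny - 2
                ym = iy - 1 if iy - 1 >= 0 else 1
                lap += phi[c, yp, ix] + phi[c, ym, ix] - 4.0 * v
                lap /= hh

                dH = (
                    0.5 * alpha * v * (v - 1.0) * (2.0 * v - 1.0)
                    - K * lap
                    + carea * v
                    + 2.0 * g * v * (sumsq[iy, ix] - v * v)
                    + v * wall_excl[iy, ix]
                )
                adh = omega * (
                    (sfx[iy, ix] - fx[c, iy, ix]) * gx[c, iy, ix]
                    + (sfy[iy, ix] - fy[c, iy, ix]) * gy[c, iy, ix]
                ) + wadh_x[iy, ix] * gx[c, iy, ix] + wadh_y[iy, ix] * gy[c, iy, ix]
                out[c, iy, ix] = (
                    -dH / gamma - adh - px[c] * gx[c, iy, ix] - py[c] * gy[c, iy, ix]
                )
    return out
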