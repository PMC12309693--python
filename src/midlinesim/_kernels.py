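"""Fused per-step computation for the simulation engine.

One pass over the cells produces the analytic forces together with the
per-cell measures the division rules and observables need (basal/apical
edge lengths, centroid x, minimum signed area).  Compiled with numba when
available; the pure-numpy routines in :mod:`midlinesim.energy` are the
reference implementation and the test suite asserts both paths agree to
machine precision.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _forces_and_measures(
    verts: np.ndarray,
    cells: np.ndarray,
    basal_y: np.ndarray,
    sign: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    V0: np.ndarray,
    h: np.ndarray,
    h_th: np.ndarray,
    ell: np.ndarray,
    forces: np.ndarray,
    basal_len: np.ndarray,
    apical_len: np.ndarray,
    cx: np.ndarray,
) -> float:
    m = cells.shape[0]
    forces[:] = 0.0
    min_area = 1e300
    for i in range(m):
        i0, i1, i2, i3 = cells[i, 0], cells[i, 1], cells[i, 2], cells[i, 3]
        x0, y0 = verts[i0, 0], verts[i0, 1]
        x1, y1 = verts[i1, 0], verts[i1, 1]
        x2, y2 = verts[i2, 0], verts[i2, 1]
        x3, y3 = verts[i3, 0], verts[i3, 1]
        cx[i] = 0.25 * (x0 + x1 + x2 + x3)
        area = 0.5 * (
            x0 * y1 - x1 * y0 + x1 * y2 - x2 * y1 + x2 * y3 - x3 * y2 + x3 * y0 - x0 * y3
        )
        if area < min_area:
            min_area = area
        # edge vectors (slot k -> k+1) and lengths
        e0x, e0y = x1 - x0, y1 - y0
        e1x, e1y = x2 - x1, y2 - y1
        e2x, e2y = x3 - x2, y3 - y2
        e3x, e3y = x0 - x3, y0 - y3
        L0 = math.sqrt(e0x * e0x + e0y * e0y)
        L1 = math.sqrt(e1x * e1x + e1y * e1y)
        L2 = math.sqrt(e2x * e2x + e2y * e2y)
        L3 = math.sqrt(e3x * e3x + e3y * e3y)
        basal_len[i] = L0
        apical_len[i] = L2
        L = L0 + L1 + L2 + L3
        # area term gradient: a (V - V0) dV/dr
        ca = a[i] * (area - V0[i])
        forces[i0, 0] -= ca * 0.5 * (y1 - y3)
        forces[i0, 1] -= ca * 0.5 * (x3 - x1)
        forces[i1, 0] -= ca * 0.5 * (y2 - y0)
        forces[i1, 1] -= ca * 0.5 * (x0 - x2)
        forces[i2, 0] -= ca * 0.5 * (y3 - y1)
        forces[i2, 1] -= ca * 0.5 * (x1 - x3)
        forces[i3, 0] -= ca * 0.5 * (y0 - y2)
        forces[i3, 1] -= ca * 0.5 * (x2 - x0)
        # perimeter term gradient: b L dL/dr with unit edge vectors
        cb = b[i] * L
        u0x, u0y = (e0x / L0, e0y / L0) if L0 > 0 else (0.0, 0.0)
        u1x, u1y = (e1x / L1, e1y / L1) if L1 > 0 else (0.0, 0.0)
        u2x, u2y = (e2x / L2, e2y / L2) if L2 > 0 else (0.0, 0.0)
        u3x, u3y = (e3x / L3, e3y / L3) if L3 > 0 else (0.0, 0.0)
        forces[i0, 0] -= cb * (u3x - u0x)
        forces[i0, 1] -= cb * (u3y - u0y)
        forces[i1, 0] -= cb * (u0x - u1x)
        forces[i1, 1] -= cb * (u0y - u1y)
        forces[i2, 0] -= cb * (u1x - u2x)
        forces[i2, 1] -= cb * (u1y - u2y)
        forces[i3, 0] -= cb * (u2x - u3x)
        forces[i3, 1] -= cb * (u2y - u3y)
        # basal adhesion (slots 0, 1) and apical repulsion (slots 2, 3)
        sgn = sign[i]
        by = basal_y[i]
        mid = 0.5 * (h_th[i] + h[i])
        for slot, vid, yv in ((0, i0, y0), (1, i1, y1)):
            dist = sgn * (yv - by)
            if dist < mid:
                fp = dist - h[i]
            elif dist < h_th[i]:
                fp = -(dist - h_th[i])
            else:
                fp = 0.0
            forces[vid, 1] -= sgn * c[i] * fp
        for slot, vid, yv in ((2, i2, y2), (3, i3, y3)):
            dist = sgn * (yv - by)
            gp = dist - ell[i] if dist >= ell[i] else 0.0
            forces[vid, 1] -= sgn * d[i] * gp
    return min_area


def forces_and_measures(
    verts: np.ndarray,
    cells: np.ndarray,
    cell_params: dict[str, np.ndarray],
    out_forces: np.ndarray,
    out_basal: np.ndarray,
    out_apical: np.ndarray,
    out_cx: np.ndarray,
) -> float:
    """Fill forces and per-cell measures; returns the minimum signed area."""
    return _forces_and_measures(
        verts,
        cells,
        cell_params["basal_y"],
        cell_params["sign"],
        cell_params["a"],
        cell_params["b"],
        cell_params["c"],
        cell_params["d"],
        cell_params["V0"],
        cell_params["h"],
        cell_params["h_th"],
        cell_params["ell"],
        out_forces,
        out_basal,
        out_apical,
        out_cx,
    )
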