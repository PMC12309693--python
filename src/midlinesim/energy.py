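"""Tissue energy and its analytic gradient.

The mechanical state of a chain of quadrilateral cells is scored by

    U = (a/2) Σ_i (V_i − V0)²  +  (b/2) Σ_i L_i²
        + c Σ_i Σ_{j ∈ B_i} f(δ_j)  +  d Σ_i Σ_{j ∈ A_i} g(δ_j)

where V_i and L_i are the area and perimeter of cell i, B_i/A_i its basal and
apical vertex pairs, and δ_j the basoapical distance of vertex j from the
tissue's basal reference line (the projection of the vertex onto the ECM
line).  ``f`` is a short-range adhesion well with minimum at the ECM position
``h`` and smooth cutoff at ``h_th``; ``g`` is a one-sided harmonic wall
confining the apical surface below the external-structure distance ``ell``.
Vertex motion follows gradient descent on U, so the force on vertex r_j is
F_j = −∂U/∂r_j, assembled here in closed form (and cross-checked against
finite differences in the test suite).

Coefficients may differ per tissue: pass a single
:class:`~midlinesim.mesh.MechanicalParams` to apply it to every cell, or a
``{tissue label: MechanicalParams}`` mapping.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np

from .mesh import (
    MechanicalParams,
    ParameterError,
    TissueMesh,
    cell_points,
    edge_lengths,
    signed_areas,
)

ParamsLike = Union[MechanicalParams, Mapping[str, MechanicalParams]]


def basal_potential_f(
    dist: np.ndarray | float, h: float, h_th: float
) -> np.ndarray | float:
    """Basal ECM-adhesion potential.

    Piecewise:  (x−h)²/2 − (h_th−h)²/4  on [0, (h_th+h)/2);
    −(x−h_th)²/2 on [(h_th+h)/2, h_th);  0 beyond h_th.
    Continuously differentiable at both breakpoints, minimum −(h_th−h)²/4
    at x = h.
    """
    if not 0 <= h < h_th:
        raise ParameterError(f"need 0 <= h < h_th, got h={h}, h_th={h_th}")
    x = np.asarray(dist, dtype=float)
    mid = 0.5 * (h_th + h)
    out = np.where(
        x < mid,
        0.5 * (x - h) ** 2 - 0.25 * (h_th - h) ** 2,
        np.where(x < h_th, -0.5 * (x - h_th) ** 2, 0.0),
    )
    return out if out.ndim else float(out)


def basal_potential_f_prime(
    dist: np.ndarray | float, h: float, h_th: float
) -> np.ndarray | float:
    """Derivative of :func:`basal_potential_f` with respect to distance."""
    if not 0 <= h < h_th:
        raise ParameterError(f"need 0 <= h < h_th, got h={h}, h_th={h_th}")
    x = np.asarray(dist, dtype=float)
    mid = 0.5 * (h_th + h)
    out = np.where(x < mid, x - h, np.where(x < h_th, -(x - h_th), 0.0))
    return out if out.ndim else float(out)


def apical_potential_g(dist: np.ndarray | float, ell: float) -> np.ndarray | float:
    """Apical repulsion: zero below ``ell``, (x−ell)²/2 at or beyond."""
    if ell <= 0:
        raise ParameterError(f"ell must be > 0, got {ell}")
    x = np.asarray(dist, dtype=float)
    out = np.where(x < ell, 0.0, 0.5 * (x - ell) ** 2)
    return out if out.ndim else float(out)


def apical_potential_g_prime(dist: np.ndarray | float, ell: float) -> np.ndarray | float:
    if ell <= 0:
        raise ParameterError(f"ell must be > 0, got {ell}")
    x = np.asarray(dist, dtype=float)
    out = np.where(x < ell, 0.0, x - ell)
    return out if out.ndim else float(out)


def _per_cell_params(mesh: TissueMesh, params: ParamsLike) -> dict[str, np.ndarray]:
    """Resolve coefficients to per-cell arrays (keys a,b,c,d,V0,h,h_th,ell)."""
    m = mesh.n_cells
    keys = ("a", "b", "c", "d", "V0", "h", "h_th", "ell")
    if isinstance(params, MechanicalParams):
        return {k: np.full(m, getattr(params, k)) for k in keys}
    out = {k: np.empty(m) for k in keys}
    for t in mesh.tissues:
        if t not in params:
            raise KeyError(f"no MechanicalParams for tissue {t!r}")
        sel = mesh.cell_tissue == t
        for k in keys:
            out[k][sel] = getattr(params[t], k)
    return out


def _basoapical_distances(mesh: TissueMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell (basal (m,2), apical (m,2)) distances and per-cell frame sign."""
    basal_y, sign = mesh.frame_arrays()
    p = cell_points(mesh)  # (m, 4, 2)
    delta = sign[:, None] * (p[..., 1] - basal_y[:, None])  # (m, 4)
    return delta[:, :2], delta[:, 2:], sign


def tissue_energy(mesh: TissueMesh, params: ParamsLike) -> float:
    """Total mechanical energy U of the mesh."""
    pc = _per_cell_params(mesh, params)
    areas = signed_areas(mesh)
    perims = edge_lengths(mesh).sum(axis=-1)
    d_bas, d_api, _ = _basoapical_distances(mesh)
    u = 0.5 * np.sum(pc["a"] * (areas - pc["V0"]) ** 2)
    u += 0.5 * np.sum(pc["b"] * perims**2)
    for k in range(2):
        u += np.sum(pc["c"] * basal_potential_f_vec(d_bas[:, k], pc["h"], pc["h_th"]))
        u += np.sum(pc["d"] * apical_potential_g_vec(d_api[:, k], pc["ell"]))
    return float(u)


def basal_potential_f_vec(x: np.ndarray, h: np.ndarray, h_th: np.ndarray) -> np.ndarray:
    """f with per-element (h, h_th); parameters assumed pre-validated."""
    mid = 0.5 * (h_th + h)
    return np.where(
        x < mid,
        0.5 * (x - h) ** 2 - 0.25 * (h_th - h) ** 2,
        np.where(x < h_th, -0.5 * (x - h_th) ** 2, 0.0),
    )


def _f_prime_vec(x: np.ndarray, h: np.ndarray, h_th: np.ndarray) -> np.ndarray:
    mid = 0.5 * (h_th + h)
    return np.where(x < mid, x - h, np.where(x < h_th, -(x - h_th), 0.0))


def apical_potential_g_vec(x: np.ndarray, ell: np.ndarray) -> np.ndarray:
    return np.where(x < ell, 0.0, 0.5 * (x - ell) ** 2)


def _g_prime_vec(x: np.ndarray, ell: np.ndarray) -> np.ndarray:
    return np.where(x < ell, 0.0, x - ell)


def tissue_forces(mesh: TissueMesh, params: ParamsLike) -> np.ndarray:
    """Analytic force F_j = −∂U/∂r_j on every vertex: (n, 2) array.

    Entries are reported for fixed x-coordinates too; the integrator masks
    them.  Shared vertices accumulate contributions from every incident
    cell.
    """
    pc = _per_cell_params(mesh, params)
    p = cell_points(mesh)  # (m, 4, 2)
    grad = np.zeros_like(p)  # dU/dr per (cell, slot)

    # area term: dU/dr = a (V - V0) dV/dr with shoelace gradient
    areas = signed_areas(mesh)
    coeff = pc["a"] * (areas - pc["V0"])  # (m,)
    nxt, prv = np.roll(p, -1, axis=1), np.roll(p, 1, axis=1)
    dA = np.empty_like(p)
    dA[..., 0] = 0.5 * (nxt[..., 1] - prv[..., 1])
    dA[..., 1] = 0.5 * (prv[..., 0] - nxt[..., 0])
    grad += coeff[:, None, None] * dA

    # perimeter term: dU/dr = b L dL/dr,  dL/dr_k = u(k,k+1->k) + u(k,k-1->k)
    edges = nxt - p  # edge k: slot k -> k+1
    lens = np.linalg.norm(edges, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(lens[..., None] > 0, edges / lens[..., None], 0.0)
    L = lens.sum(axis=-1)
    dL = np.roll(units, 1, axis=1) - units  # unit(prev edge) - unit(next edge)
    grad += (pc["b"] * L)[:, None, None] * dL

    # adhesion/repulsion: act on y only, through the basoapical distance
    d_bas, d_api, sign = _basoapical_distances(mesh)
    for k in range(2):
        grad[:, k, 1] += sign * pc["c"] * _f_prime_vec(d_bas[:, k], pc["h"], pc["h_th"])
        grad[:, 2 + k, 1] += sign * pc["d"] * _g_prime_vec(d_api[:, k], pc["ell"])

    forces = np.zeros_like(mesh.vertices)
    np.add.at(forces, mesh.cells, -grad)
    return forces


def edge_elastic_energy(mesh: TissueMesh, cell_id: int, b: float) -> float:
    """Apical/basal edge elastic energy U_i = b (L_apical² + L_basal²)/2."""
    mesh._check_cell_id(cell_id)
    el = edge_lengths(mesh)[cell_id]
    return float(0.5 * b * (el[0] ** 2 + el[2] ** 2))


def edge_elastic_energies(mesh: TissueMesh, b: np.ndarray | float) -> np.ndarray:
    """Vectorized :func:`edge_elastic_energy` for all cells."""
    el = edge_lengths(mesh)
    return 0.5 * np.asarray(b) * (el[:, 0] ** 2 + el[:, 2] ** 2)
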