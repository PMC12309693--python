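"""Shared-vertex quadrilateral meshes for linear cell chains.

A tissue is a chain of quadrilateral cells that share vertices along their
common lateral edges.  Each cell stores four vertex indices in a fixed cyclic
order — anterior-basal, posterior-basal, posterior-apical, anterior-apical —
so the basal pair is always ``vertex_ids[:2]`` and the apical pair
``vertex_ids[2:]``.  Orientation relative to the extracellular matrix (ECM)
is carried per cell by an :class:`EcmFrame`: a basal reference line (a
horizontal line ``y = basal_y``) plus the sign of the apical direction, which
lets mirrored tissues (floorplate above the notochord, hypochord below)
coexist in one global coordinate system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """A cell polygon is degenerate, inverted, or self-intersecting."""


class ParameterError(ValueError):
    """A model parameter violates its admissibility constraint."""


# cyclic-order slot names, for error messages and serialization headers
QUAD_SLOTS = ("anterior_basal", "posterior_basal", "posterior_apical", "anterior_apical")


@dataclass(frozen=True)
class EcmFrame:
    """Orientation of a tissue relative to its adhesion substrate.

    Parameters
    ----------
    basal_y
        y-coordinate of the basal reference line (the ECM the tissue
        adheres to).  Basoapical distances are measured from this line.
    apical_sign
        +1 if the apical surface lies at larger y than the basal line,
        -1 for a mirrored tissue.
    """

    basal_y: float = 0.0
    apical_sign: int = 1

    def __post_init__(self) -> None:
        if self.apical_sign not in (-1, 1):
            raise ParameterError(f"apical_sign must be +1 or -1, got {self.apical_sign}")

    def basoapical_distance(self, y: np.ndarray | float) -> np.ndarray | float:
        """Signed distance from the basal line, positive toward apical."""
        return self.apical_sign * (np.asarray(y) - self.basal_y)


@dataclass(frozen=True)
class MechanicalParams:
    """Energy coefficients and geometry constants of one tissue.

    ``a`` penalizes deviation of cell area from the target ``V0``; ``b`` is
    the perimeter-contraction coefficient; ``c`` and ``d`` scale basal-ECM
    adhesion and apical repulsion.  ``h`` is the rest position of the
    adhesion minimum above the basal line, ``h_th`` the adhesion cutoff,
    ``ell`` the apical confinement distance.  ``tau`` (viscosity) and
    ``sigma`` (noise amplitude) enter the overdamped Langevin dynamics.
    """

    a: float = 4.0
    b: float = 0.05
    c: float = 5.0
    d: float = 5.0
    V0: float = 1.0
    h: float = 0.05
    h_th: float = 0.5
    ell: float = 1.2
    tau: float = 1.0
    sigma: float = 0.01

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "tau"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.V0 <= 0:
            raise ParameterError(f"V0 must be > 0, got {self.V0}")
        if not 0 <= self.h < self.h_th:
            raise ParameterError(f"need 0 <= h < h_th, got h={self.h}, h_th={self.h_th}")
        if self.ell <= 0:
            raise ParameterError(f"ell must be > 0, got {self.ell}")


class TissueMesh:
    """Vertex table plus quadrilateral cells, possibly spanning several tissues.

    Attributes
    ----------
    vertices : (n, 2) float array
        Vertex positions; column 0 is the anterior-posterior (x) axis,
        column 1 the basoapical (y) axis of the global frame.
    cells : (m, 4) int array
        Vertex indices per cell in the fixed cyclic order.
    fixed_x : (n,) bool array
        Vertices whose x-coordinate is immobilized (anterior anchors).
    cell_tissue : (m,) array of str
        Tissue label of each cell (e.g. ``"FP"``, ``"HC"``, ``"noto"``).
    frames : dict[str, EcmFrame]
        ECM frame per tissue label.
    """

    def __init__(
        self,
        vertices: np.ndarray,
        cells: np.ndarray,
        fixed_x: np.ndarray | None = None,
        cell_tissue: np.ndarray | list[str] | None = None,
        frames: dict[str, EcmFrame] | None = None,
        validate: bool = True,
    ) -> None:
        self.vertices = np.array(vertices, dtype=float)
        self.cells = np.array(cells, dtype=np.intp).reshape(-1, 4)
        n = len(self.vertices)
        if fixed_x is None:
            fixed_x = np.zeros(n, dtype=bool)
        self.fixed_x = np.asarray(fixed_x, dtype=bool)
        if cell_tissue is None:
            cell_tissue = ["tissue"] * len(self.cells)
        self.cell_tissue = np.asarray(cell_tissue, dtype=object)
        self.frames = dict(frames) if frames else {t: EcmFrame() for t in self.tissues}
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.cell_tissue:
            seen.setdefault(t)
        return list(seen)

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            self.vertices.copy(),
            self.cells.copy(),
            self.fixed_x.copy(),
            self.cell_tissue.copy(),
            dict(self.frames),
            validate=False,
        )

    def cells_of(self, tissue: str) -> np.ndarray:
        """Indices of the cells belonging to ``tissue``."""
        idx = np.flatnonzero(self.cell_tissue == tissue)
        if idx.size == 0:
            raise KeyError(f"unknown tissue label {tissue!r}")
        return idx

    def frame_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (basal_y, apical_sign) arrays resolved from ``frames``."""
        basal_y = np.empty(self.n_cells)
        sign = np.empty(self.n_cells)
        for t in self.tissues:
            fr = self.frames[t]
            sel = self.cell_tissue == t
            basal_y[sel] = fr.basal_y
            sign[sel] = fr.apical_sign
        return basal_y, sign

    # ------------------------------------------------------------------
    def _check_cell_id(self, cell_id: int) -> int:
        cell_id = int(cell_id)
        if not 0 <= cell_id < self.n_cells:
            raise KeyError(f"unknown cell id {cell_id} (mesh has {self.n_cells} cells)")
        return cell_id

    def validate(self) -> None:
        """Raise on invariant violations (bad indices, degenerate cells)."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("non-finite vertex coordinates")
        if self.cells.size and (self.cells.min() < 0 or self.cells.max() >= self.n_vertices):
            raise ValueError("cell vertex index out of range")
        if len(self.fixed_x) != self.n_vertices:
            raise ValueError("fixed_x length mismatch")
        if len(self.cell_tissue) != self.n_cells:
            raise ValueError("cell_tissue length mismatch")
        for t in self.tissues:
            if t not in self.frames:
                raise ValueError(f"no EcmFrame for tissue {t!r}")
        for i in range(self.n_cells):
            validate_cell(self, i)

    # ------------------------------------------------------------------
    # serialization: documented CSV/JSON dialect, see docs/methods.md
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Mesh as (vertex table, cell table) DataFrames."""
        vdf = pd.DataFrame(
            {
                "id": np.arange(self.n_vertices),
                "x": self.vertices[:, 0],
                "y": self.vertices[:, 1],
                "fixed": self.fixed_x.astype(int),
            }
        )
        cdf = pd.DataFrame(self.cells, columns=["v0", "v1", "v2", "v3"])
        cdf.insert(0, "id", np.arange(self.n_cells))
        cdf["tissue"] = self.cell_tissue
        return vdf, cdf

    def to_csv(self, vertex_path: str | Path, cell_path: str | Path) -> None:
        vdf, cdf = self.to_frames()
        vdf.to_csv(vertex_path, index=False)
        cdf.to_csv(cell_path, index=False)

    def to_json_dict(self) -> dict:
        vdf, cdf = self.to_frames()
        return {
            "vertices": vdf.to_dict(orient="list"),
            "cells": cdf.to_dict(orient="list"),
            "frames": {
                t: {"basal_y": fr.basal_y, "apical_sign": fr.apical_sign}
                for t, fr in self.frames.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def from_frames(
        cls, vdf: pd.DataFrame, cdf: pd.DataFrame, frames: dict[str, EcmFrame] | None = None
    ) -> "TissueMesh":
        vdf = vdf.sort_values("id")
        cdf = cdf.sort_values("id")
        return cls(
            vdf[["x", "y"]].to_numpy(),
            cdf[["v0", "v1", "v2", "v3"]].to_numpy(),
            vdf["fixed"].to_numpy().astype(bool),
            cdf["tissue"].to_numpy(dtype=object),
            frames,
        )

    @classmethod
    def from_csv(
        cls,
        vertex_path: str | Path,
        cell_path: str | Path,
        frames: dict[str, EcmFrame] | None = None,
    ) -> "TissueMesh":
        return cls.from_frames(pd.read_csv(vertex_path), pd.read_csv(cell_path), frames)

    @classmethod
    def from_json_dict(cls, doc: dict) -> "TissueMesh":
        frames = {
            t: EcmFrame(d["basal_y"], d["apical_sign"]) for t, d in doc.get("frames", {}).items()
        }
        return cls.from_frames(
            pd.DataFrame(doc["vertices"]), pd.DataFrame(doc["cells"]), frames or None
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TissueMesh":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# geometry


def cell_points(mesh: TissueMesh, cell_id: int | None = None) -> np.ndarray:
    """Vertex coordinates per cell: (m, 4, 2), or (4, 2) for one cell."""
    if cell_id is None:
        return mesh.vertices[mesh.cells]
    return mesh.vertices[mesh.cells[mesh._check_cell_id(cell_id)]]


def signed_areas(mesh: TissueMesh) -> np.ndarray:
    """Shoelace signed area of every cell; positive for valid orientation."""
    p = cell_points(mesh)
    x, y = p[..., 0], p[..., 1]
    xn, yn = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    return 0.5 * np.sum(x * yn - xn * y, axis=-1)


def cell_areas(mesh: TissueMesh) -> np.ndarray:
    """Areas of all cells (signed areas; valid cells are positive)."""
    return signed_areas(mesh)


def cell_area(mesh: TissueMesh, cell_id: int) -> float:
    """Polygon area of one cell.

    Raises :class:`GeometryError` if the quad is degenerate (zero area) or
    inverted/self-intersecting (non-positive signed area).
    """
    mesh._check_cell_id(cell_id)
    area = float(signed_areas(mesh)[cell_id])
    if area <= 0:
        raise GeometryError(f"cell {cell_id} has non-positive signed area {area:g}")
    return area


def edge_lengths(mesh: TissueMesh) -> np.ndarray:
    """Lengths of the four cyclic edges of every cell: (m, 4).

    Edge k joins slot k to slot k+1 (mod 4): edge 0 is basal, edge 2 apical,
    edges 1 and 3 the posterior and anterior lateral edges.
    """
    p = cell_points(mesh)
    return np.linalg.norm(np.roll(p, -1, axis=1) - p, axis=-1)


def cell_perimeters(mesh: TissueMesh) -> np.ndarray:
    return edge_lengths(mesh).sum(axis=-1)


def cell_perimeter(mesh: TissueMesh, cell_id: int) -> float:
    """Sum of the four edge lengths of one cell in cyclic order."""
    mesh._check_cell_id(cell_id)
    return float(cell_perimeters(mesh)[cell_id])


def cell_centroids_x(mesh: TissueMesh) -> np.ndarray:
    """x-coordinate of each cell's vertex centroid."""
    return cell_points(mesh)[..., 0].mean(axis=-1)


def basal_apical_lengths(mesh: TissueMesh) -> tuple[np.ndarray, np.ndarray]:
    """(basal, apical) edge lengths of every cell."""
    el = edge_lengths(mesh)
    return el[:, 0], el[:, 2]


def validate_cell(mesh: TissueMesh, cell_id: int) -> None:
    """Check one cell: distinct indices, simple polygon, positive area."""
    ids = mesh.cells[mesh._check_cell_id(cell_id)]
    if len(set(ids.tolist())) != 4:
        raise GeometryError(f"cell {cell_id} has repeated vertex indices {ids.tolist()}")
    pts = mesh.vertices[ids]
    area = 0.5 * np.sum(
        pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]
    )
    if area <= 0:
        raise GeometryError(f"cell {cell_id} has non-positive signed area {area:g}")
    poly = Polygon(pts)
    if not poly.is_simple or not poly.is_valid:
        raise GeometryError(f"cell {cell_id} is self-intersecting")
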