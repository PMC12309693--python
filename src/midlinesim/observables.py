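"""Read-outs of simulation runs.

Holds the trace containers every simulation produces (time-stamped mesh
snapshots plus division events) and the derived quantities used to
characterize runs: tissue lengths, spatial uniformity of divisions
(Kolmogorov–Smirnov distance to uniform), anterior-gap flags, the relative
length mismatch between follower tissues and the notochord, and simulated
kymographs that close the loop with the kymograph-velocity estimator in
:mod:`midlinesim.quantify`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import TissueMesh, basal_apical_lengths

#: sentinel returned by :func:`uniformity_statistic` when no events qualify
NO_EVENTS = float("nan")


@dataclass(frozen=True)
class DivisionEvent:
    """One cell division: when, in which tissue, and where along the axis.

    ``relative_position`` is the dividing cell's centroid x normalized by the
    tissue's extent at the time of division, so it lies in [0, 1] with 1 the
    posterior end.
    """

    t: float
    tissue: str
    cell_centroid_x: float
    relative_position: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.relative_position <= 1 + 1e-9:
            raise ValueError(f"relative_position {self.relative_position} outside [0, 1]")


@dataclass
class SimulationTrace:
    """Snapshots, division events and config echo of one simulation run."""

    frames: list[tuple[float, TissueMesh]] = field(default_factory=list)
    events: list[DivisionEvent] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    seed: int | None = None
    #: diagnostic set when the run left model validity and was stopped early
    aborted: str | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames])

    @property
    def final_mesh(self) -> TissueMesh:
        return self.frames[-1][1]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t": e.t,
                    "tissue": e.tissue,
                    "cell_centroid_x": e.cell_centroid_x,
                    "relative_position": e.relative_position,
                }
                for e in self.events
            ],
            columns=["t", "tissue", "cell_centroid_x", "relative_position"],
        )

    def save(self, out_dir: str | Path) -> None:
        """Write frames.csv, divisions.csv and summary.json to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for t, mesh in self.frames:
            vdf, cdf = mesh.to_frames()
            cdf = cdf.rename(columns={"id": "cell_id"})
            cdf["t"] = t
            for k, col in zip(("v0", "v1", "v2", "v3"), range(4)):
                pts = mesh.vertices[mesh.cells[:, col]]
                cdf[f"{k}_x"], cdf[f"{k}_y"] = pts[:, 0], pts[:, 1]
            rows.append(cdf)
        pd.concat(rows, ignore_index=True).to_csv(out / "frames.csv", index=False)
        self.events_frame().to_csv(out / "divisions.csv", index=False)
        last = self.final_mesh
        summary = {
            "seed": self.seed,
            "config": self.config_echo,
            "t_final": self.frames[-1][0],
            "n_cells_final": int(last.n_cells),
            "n_divisions": len(self.events),
            "final_lengths": {t: tissue_length(last, t) for t in last.tissues},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


# ----------------------------------------------------------------------


def tissue_extent(mesh: TissueMesh, tissue: str) -> tuple[float, float]:
    """(anterior-most, posterior-most) vertex x of one tissue."""
    vids = np.unique(mesh.cells[mesh.cells_of(tissue)])
    xs = mesh.vertices[vids, 0]
    return float(xs.min()), float(xs.max())


def tissue_length(mesh: TissueMesh, tissue: str) -> float:
    """Axis extent of a tissue: posterior-most minus anterior-most vertex x."""
    lo, hi = tissue_extent(mesh, tissue)
    return hi - lo


def length_series(trace: SimulationTrace, tissue: str) -> pd.Series:
    """Tissue length at every frame, indexed by time."""
    return pd.Series(
        [tissue_length(mesh, tissue) for _, mesh in trace.frames],
        index=trace.times,
        name=tissue,
    )


def uniformity_statistic(
    events: list[DivisionEvent] | pd.DataFrame,
    t_min: float = 0.0,
    tissue: str | None = None,
) -> float:
    """Kolmogorov–Smirnov distance between division positions and Uniform(0,1).

    0 means divisions are spatially unbiased along the axis; 1 means they are
    concentrated at a single end.  Events before ``t_min`` are ignored.
    Returns NaN (with a warning) when no event qualifies.
    """
    df = events if isinstance(events, pd.DataFrame) else _events_df(events)
    sel = df["t"] >= t_min
    if tissue is not None:
        sel &= df["tissue"] == tissue
    pos = df.loc[sel, "relative_position"].to_numpy()
    if pos.size == 0:
        warnings.warn("no division events after t_min; uniformity undefined", stacklevel=2)
        return NO_EVENTS
    return float(stats.kstest(pos, stats.uniform.cdf).statistic)


def _events_df(events: list[DivisionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.t, e.tissue, e.relative_position) for e in events],
        columns=["t", "tissue", "relative_position"],
    )


def posterior_fraction(
    events: list[DivisionEvent] | pd.DataFrame,
    t_min: float = 0.0,
    tissue: str | None = None,
    quartile: float = 0.75,
) -> float:
    """Fraction of divisions (after ``t_min``) in the posterior quartile."""
    df = events if isinstance(events, pd.DataFrame) else _events_df(events)
    sel = df["t"] >= t_min
    if tissue is not None:
        sel &= df["tissue"] == tissue
    pos = df.loc[sel, "relative_position"].to_numpy()
    if pos.size == 0:
        return NO_EVENTS
    return float(np.mean(pos >= quartile))


def gap_flag(
    mesh: TissueMesh,
    tissue: str,
    rupture_factor: float = 3.0,
    initial_basal_length: float = 1.0,
) -> np.ndarray:
    """Cells whose basal edge exceeds ``rupture_factor`` × the initial length.

    The shared-vertex chain cannot physically separate, so over-stretched
    basal edges serve as the proxy for rupture/gaps at the anterior end.
    Returns the flagged cell ids (global indices into ``mesh.cells``).
    """
    if rupture_factor <= 1:
        raise ValueError(f"rupture_factor must be > 1, got {rupture_factor}")
    ids = mesh.cells_of(tissue)
    basal, _ = basal_apical_lengths(mesh)
    return ids[basal[ids] > rupture_factor * initial_basal_length]


def first_gap_time(
    trace: SimulationTrace,
    tissue: str,
    rupture_factor: float = 3.0,
    initial_basal_length: float = 1.0,
    anterior_only: float | None = None,
) -> float:
    """Earliest frame time with a flagged cell, or inf if none.

    With ``anterior_only`` set (a fraction in (0, 1]), only cells whose
    centroid lies in the anterior ``anterior_only`` of the tissue extent
    count, matching the anterior-gap phenotype.
    """
    from .mesh import cell_centroids_x

    for t, mesh in trace.frames:
        flagged = gap_flag(mesh, tissue, rupture_factor, initial_basal_length)
        if flagged.size and anterior_only is not None:
            lo, hi = tissue_extent(mesh, tissue)
            cx = cell_centroids_x(mesh)[flagged]
            flagged = flagged[(cx - lo) <= anterior_only * max(hi - lo, 1e-12)]
        if flagged.size:
            return t
    return math.inf


def length_mismatch_series(
    trace: SimulationTrace, leader: str = "noto", followers: tuple[str, ...] = ("FP", "HC")
) -> pd.DataFrame:
    """|L_follower − L_leader| / L_leader at every frame, per follower tissue."""
    out = {}
    times = trace.times
    l_leader = np.array([tissue_length(m, leader) for _, m in trace.frames])
    if np.any(l_leader <= 0):
        raise ZeroDivisionError("leader tissue has non-positive length in some frame")
    for f in followers:
        lf = np.array([tissue_length(m, f) for _, m in trace.frames])
        out[f] = np.abs(lf - l_leader) / l_leader
    return pd.DataFrame(out, index=times)


def export_kymograph(
    trace: SimulationTrace, tissue: str, n_bins: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-boundary occupancy raster: rows = frames, columns = spatial bins.

    Lateral cell boundaries (shared vertex x positions, averaged over the
    basal/apical pair) are deposited into ``n_bins`` equal bins spanning the
    union extent over all frames, with linear interpolation between the two
    neighboring bins.  Moving boundaries appear as slanted lines whose slope
    is the boundary velocity.

    Returns ``(image, times, bin_centers)``.
    """
    if len(trace.frames) < 2:
        raise ValueError("kymograph needs at least 2 frames")
    boundary_sets = []
    for _, mesh in trace.frames:
        cells = mesh.cells[mesh.cells_of(tissue)]
        pts = mesh.vertices[cells]  # (m, 4, 2)
        # lateral boundaries: anterior edge midpoints plus the posterior end
        xs = 0.5 * (pts[:, 0, 0] + pts[:, 3, 0])
        xs = np.append(xs, 0.5 * (pts[:, 1, 0] + pts[:, 2, 0]).max())
        boundary_sets.append(np.sort(xs))
    lo = min(b.min() for b in boundary_sets)
    hi = max(b.max() for b in boundary_sets)
    span = max(hi - lo, 1e-12)
    image = np.zeros((len(boundary_sets), n_bins))
    for row, xs in enumerate(boundary_sets):
        u = np.clip((xs - lo) / span * (n_bins - 1), 0, n_bins - 1)
        left = np.floor(u).astype(int)
        frac = u - left
        np.add.at(image[row], left, 1 - frac)
        np.add.at(image[row], np.minimum(left + 1, n_bins - 1), frac)
    centers = lo + (np.arange(n_bins) + 0.5) / n_bins * span
    return image, trace.times, centers
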