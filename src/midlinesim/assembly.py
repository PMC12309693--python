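"""Three-tissue midline assemblies and scenario presets.

The notochord occupies the central band, the floorplate (FP) sits above it
(basal side down, adhering to the notochord's apical surface) and the
hypochord (HC) mirrored below.  The notochord is the leader: it elongates by
clocked division of its posterior-most cell, abstracting the progenitor pool
that adds cells at the growing tip.  FP and HC are followers: they migrate
posteriorly with graded activity and divide when stretched.  Tethering the
posterior ends — merging the posterior basal vertex of the posterior-most
follower cell with the matching posterior vertex of the notochord into one
shared vertex — couples the tissues mechanically, the model's counterpart of
cadherin-mediated adhesion at the posterior termini.

Scenario presets reproduce, in kind, the simulation figures of the study:
three single-tissue migration modes (posterior-only, uniform, graded) and
the tethered/untethered leader-follower assemblies with a fast (D = 0.8) or
slow (D = 1.2) notochord clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import observables as obs
from .dynamics import (
    CellStates,
    ClockDivisionSpec,
    DivisionParams,
    IntegratorSpec,
    MigrationParams,
    SimState,
    SingleTissueConfig,
    TissueRole,
    run_single_tissue,
    simulate,
)
from .energy import tissue_forces
from .mesh import EcmFrame, MechanicalParams, TissueMesh
from .synthetic import make_initial_mesh

FOLLOWERS = ("FP", "HC")
LEADER = "noto"

SCENARIO_NAMES = (
    "s7_posterior_only",
    "s7_uniform",
    "s7_graded",
    "fig5_fast_leader",
    "fig5_slow_leader",
)


@dataclass(frozen=True)
class TetherBond:
    """One follower-leader shared-vertex bond (ids into the vertex table)."""

    follower_vertex: int
    leader_vertex: int


@dataclass(frozen=True)
class AssemblySpec:
    """Geometry, parameters and drives of a three-tissue assembly.

    The notochord chain starts with twice the follower cell count at half
    the cell width, so all three tissues share the initial extent
    ``n_follower * cell_width``.
    """

    n_follower: int = 8
    tethered: bool = True
    noto_D: float = 0.8
    follower_migration: MigrationParams = field(default_factory=MigrationParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    noto_mechanics: MechanicalParams | None = None
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    cell_width: float = 1.0
    cell_height: float = 1.0
    frames: dict[str, EcmFrame] | None = None

    def __post_init__(self) -> None:
        if self.n_follower < 2:
            raise ValueError(f"n_follower must be >= 2, got {self.n_follower}")

    @property
    def n_noto(self) -> int:
        return 2 * self.n_follower

    def default_frames(self) -> dict[str, EcmFrame]:
        """Band layout: notochord on y=0, FP above its apical face, HC mirrored."""
        h, ch = self.mechanics.h, self.cell_height
        return {
            LEADER: EcmFrame(0.0, 1),
            "FP": EcmFrame(ch + h, 1),
            "HC": EcmFrame(0.0, -1),
        }

    def tissue_params(self) -> dict[str, MechanicalParams]:
        """Per-tissue mechanics.

        Unless ``noto_mechanics`` is given, the notochord derives from the
        follower mechanics with its target area matched to its half-width
        cells and a much higher area/perimeter stiffness: the vacuolated
        notochord is the rigid rod of the axis, and the stiffness keeps its
        elongation tracking the division clock instead of piling compressed
        daughters at the tip.
        """
        noto_v0 = 0.5 * self.cell_width * self.cell_height
        noto = self.noto_mechanics or replace(self.mechanics, V0=noto_v0, a=16.0, b=0.2)
        return {"FP": self.mechanics, "HC": self.mechanics, LEADER: noto}


def build_assembly(spec: AssemblySpec) -> tuple[SimState, list[TetherBond]]:
    """Initial three-chain state; tether bonds are merged when requested.

    Each tissue's two anterior-most vertices are x-anchored.  Raises on
    frame layouts whose tissue bands overlap vertically.
    """
    frames = spec.frames or spec.default_frames()
    _check_band_overlap(frames, spec.mechanics.h, spec.cell_height)
    parts = []
    for tissue in (LEADER, "FP", "HC"):
        n = spec.n_noto if tissue == LEADER else spec.n_follower
        w = spec.cell_width / 2 if tissue == LEADER else spec.cell_width
        parts.append(
            make_initial_mesh(
                n,
                cell_width=w,
                cell_height=spec.cell_height,
                h=spec.mechanics.h,
                frame=frames[tissue],
                tissue=tissue,
            )
        )
    mesh = _concatenate(parts, frames)
    state = SimState(mesh, CellStates(mesh.n_cells))
    bonds = []
    if spec.tethered:
        for follower in FOLLOWERS:
            bond = locate_tether(mesh, follower)
            merge_tether_vertices(state, bond)
            bonds.append(locate_tether(mesh, follower))
    return state, bonds


def _concatenate(parts: list[TissueMesh], frames: dict[str, EcmFrame]) -> TissueMesh:
    verts = np.vstack([p.vertices for p in parts])
    offs = np.cumsum([0] + [p.n_vertices for p in parts[:-1]])
    cells = np.vstack([p.cells + o for p, o in zip(parts, offs)])
    fixed = np.concatenate([p.fixed_x for p in parts])
    tissue = np.concatenate([p.cell_tissue for p in parts])
    return TissueMesh(verts, cells, fixed, tissue, frames)


def _check_band_overlap(frames: dict[str, EcmFrame], h: float, cell_height: float) -> None:
    bands = {}
    for t, fr in frames.items():
        lo = fr.basal_y + fr.apical_sign * h
        hi = lo + fr.apical_sign * cell_height
        bands[t] = (min(lo, hi), max(lo, hi))
    labels = list(bands)
    for i, ti in enumerate(labels):
        for tj in labels[i + 1 :]:
            (a0, a1), (b0, b1) = bands[ti], bands[tj]
            if a0 < b1 - 1e-9 and b0 < a1 - 1e-9:
                raise ValueError(f"tissue bands of {ti!r} and {tj!r} overlap vertically")


def _posterior_vertices(mesh: TissueMesh, tissue: str) -> tuple[int, int]:
    """(basal, apical) vertex ids of the posterior-most cell of a tissue."""
    ids = mesh.cells_of(tissue)
    cx = mesh.vertices[mesh.cells[ids]][..., 0].mean(axis=1)
    cell = mesh.cells[ids[np.argmax(cx)]]
    sgn = mesh.frames[tissue].apical_sign
    if sgn > 0:
        return int(cell[1]), int(cell[2])  # posterior-basal, posterior-apical
    return int(cell[0]), int(cell[3])


def locate_tether(mesh: TissueMesh, follower: str) -> TetherBond:
    """Current bond endpoints for one follower: its posterior basal vertex and
    the notochord posterior vertex on the matching side (apical for FP above,
    basal for HC below)."""
    fb, _ = _posterior_vertices(mesh, follower)
    nb, na = _posterior_vertices(mesh, LEADER)
    leader_vertex = na if mesh.frames[follower].basal_y > mesh.frames[LEADER].basal_y else nb
    return TetherBond(fb, leader_vertex)


def merge_tether_vertices(state: SimState, bond: TetherBond) -> SimState:
    """Fuse the two bond vertices into one shared vertex (in place).

    The merged vertex sits at the midpoint of the two and accumulates force
    contributions from every incident cell of both tissues.  Merging an
    already-merged bond is an idempotent no-op (with a warning).  Division
    of a posterior-most cell keeps the shared vertex on the new
    posterior-most cells automatically, because midpoint division never
    replaces a cell's posterior vertices.
    """
    mesh = state.mesh
    keep, drop = sorted((bond.follower_vertex, bond.leader_vertex))
    if keep == drop:
        warnings.warn("tether vertices already merged; no-op", stacklevel=2)
        return state
    mesh.vertices[keep] = 0.5 * (mesh.vertices[keep] + mesh.vertices[drop])
    mesh.fixed_x[keep] = mesh.fixed_x[keep] or mesh.fixed_x[drop]
    cells = mesh.cells
    cells[cells == drop] = keep
    cells[cells > drop] -= 1
    mesh.vertices = np.delete(mesh.vertices, drop, axis=0)
    mesh.fixed_x = np.delete(mesh.fixed_x, drop)
    return state


# ----------------------------------------------------------------------


def run_assembly(
    spec: AssemblySpec,
    t_end: float = 100.0,
    seed: int | None = None,
    snapshot_every: float = 1.0,
    on_invalid_geometry: str = "raise",
) -> obs.SimulationTrace:
    """Co-evolve the three tissues to ``t_end`` and record the trace.

    Followers are driven by graded migration plus stretch-triggered
    division; the notochord by posterior-tip clock division with period
    ``noto_D``.  Tether bonds (when present) are plain shared vertices, so
    force balance across tissues needs no extra machinery.
    """
    integ = spec.integrator if seed is None else replace(spec.integrator, seed=seed)
    state, _ = build_assembly(spec)
    roles = {
        "FP": TissueRole(migration=spec.follower_migration, division=spec.division),
        "HC": TissueRole(migration=spec.follower_migration, division=spec.division),
        LEADER: TissueRole(clock=ClockDivisionSpec(spec.noto_D, scope="posterior_most")),
    }
    echo = {
        "n_follower": spec.n_follower,
        "tethered": spec.tethered,
        "noto_D": spec.noto_D,
        "migration": vars(spec.follower_migration).copy(),
        "division": vars(spec.division).copy(),
        "mechanics": vars(spec.mechanics).copy(),
        "integrator": vars(integ).copy(),
        "t_end": t_end,
    }
    return simulate(
        state,
        spec.tissue_params(),
        roles,
        integ,
        t_end,
        snapshot_every,
        config_echo=echo,
        on_invalid_geometry=on_invalid_geometry,
    )


def assembly_forces(state: SimState, spec: AssemblySpec) -> np.ndarray:
    """Analytic forces on the full assembly (shared vertices accumulate both
    tissues' energy gradients)."""
    return tissue_forces(state.mesh, spec.tissue_params())


# ----------------------------------------------------------------------
# scenario presets


def scenario(
    name: str,
    tethered: bool = True,
    seed: int = 0,
    t_end: float | None = None,
    t_min_report: float = 50.0,
    **overrides,
) -> tuple[obs.SimulationTrace, dict]:
    """Run one canonical scenario and report its characteristic observables.

    Single-tissue presets (``s7_posterior_only``, ``s7_uniform``,
    ``s7_graded``) run one follower chain of 32 cells with the named
    migration gradient; assembly presets (``fig5_fast_leader``,
    ``fig5_slow_leader``) run the tethered or untethered three-tissue model
    with notochord clock period 0.8 or 1.2.  ``overrides`` patch the
    underlying config (e.g. ``vmax=0.4``, ``exponent=1.2``).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if name.startswith("s7_"):
        trace = _run_s7(name.removeprefix("s7_"), seed, t_end or 100.0, **overrides)
        report = {
            "scenario": name,
            "seed": seed,
            "aborted": trace.aborted,
            "n_divisions": len(trace.events),
            "uniformity_statistic": obs.uniformity_statistic(trace.events, t_min=0.0),
            "posterior_quartile_fraction": obs.posterior_fraction(trace.events),
            "first_anterior_gap_time": obs.first_gap_time(
                trace, trace.final_mesh.tissues[0], anterior_only=0.25
            ),
            "final_length": obs.tissue_length(trace.final_mesh, trace.final_mesh.tissues[0]),
        }
        return trace, report
    noto_D = 0.8 if name == "fig5_fast_leader" else 1.2
    mig_over = {k: v for k, v in overrides.items() if k in ("vmax", "eta", "exponent")}
    # follower pace set so the two clock presets straddle it: the followers
    # lag a fast leader (D = 0.8) and outpace a slow one (D = 1.2)
    mig_over.setdefault("vmax", 1.0)
    spec_over = {k: v for k, v in overrides.items() if k not in mig_over}
    spec = AssemblySpec(
        tethered=tethered,
        noto_D=noto_D,
        follower_migration=MigrationParams.from_preset("graded", **mig_over),
        **spec_over,
    )
    trace = run_assembly(spec, t_end=t_end or 100.0, seed=seed, on_invalid_geometry="stop")
    mism = obs.length_mismatch_series(trace)
    report = {
        "scenario": name,
        "tethered": tethered,
        "seed": seed,
        "noto_D": noto_D,
        "n_divisions": len(trace.events),
        "max_mismatch": float(mism.to_numpy().max()),
        "final_mismatch": {t: float(mism[t].iloc[-1]) for t in mism.columns},
        "final_lengths": {
            t: obs.tissue_length(trace.final_mesh, t) for t in trace.final_mesh.tissues
        },
        "posterior_quartile_fraction": {
            f: obs.posterior_fraction(trace.events, t_min=t_min_report, tissue=f)
            for f in FOLLOWERS
        },
    }
    return trace, report


def _run_s7(preset: str, seed: int, t_end: float, **overrides) -> obs.SimulationTrace:
    """Single-tissue scenario run; stops (with diagnostic) on invalid geometry."""
    mig_over = {k: v for k, v in overrides.items() if k in ("vmax", "eta")}
    exponent = overrides.get("exponent")
    if exponent is not None:
        migration = MigrationParams(exponent=exponent, **mig_over)
    else:
        migration = MigrationParams.from_preset(preset, **mig_over)
    cfg_over = {
        k: v
        for k, v in overrides.items()
        if k not in ("vmax", "eta", "exponent")
    }
    config = SingleTissueConfig(
        migration=migration,
        integrator=IntegratorSpec(seed=seed),
        t_end=t_end,
        **cfg_over,
    )
    return run_single_tissue(config, on_invalid_geometry="stop")


def sweep_alpha(
    exponents: tuple[float, ...] = (0.85, 1.0, 1.2, 1.5),
    seeds: tuple[int, ...] = (0, 1, 2),
    t_end: float = 100.0,
    **overrides,
) -> list[dict]:
    """Uniformity of division positions across graded-gradient shapes.

    Runs the graded single-tissue scenario for every (exponent, seed) cell
    and reports the division-position uniformity statistic, checking that
    spatially distributed proliferation is robust to the gradient shape.
    """
    out = []
    for exp in exponents:
        for seed in seeds:
            trace = _run_s7("graded", seed, t_end, exponent=exp, **overrides)
            out.append(
                {
                    "exponent": exp,
                    "seed": seed,
                    "n_divisions": len(trace.events),
                    "uniformity_statistic": obs.uniformity_statistic(trace.events),
                }
            )
    return out
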