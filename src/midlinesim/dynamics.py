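"""Time evolution of the vertex model.

Three coupled processes advance the state each step of size ``dt``:

1. **Migration forces.**  Each migratory cell carries a force ``v_i`` along
   the anterior-posterior axis, relaxing toward its position-dependent
   target ``w_i`` (the migration activity) with time constant ``eta``:
   ``eta dv_i/dt = -v_i + w_i``.  Integrated with one classical 4th-order
   Runge-Kutta step per time step, ``w_i`` frozen within the step.
2. **Vertex positions.**  Overdamped Langevin dynamics
   ``tau dr_j/dt = F_j + sigma xi(t)`` integrated with Euler-Maruyama:
   increments ``(F_j/tau) dt + (sigma/tau) sqrt(dt) N(0, 1)`` per free
   coordinate.  ``v_i`` is applied to the posterior basal vertex of cell i.
   x-coordinates of anchored (anterior-most) vertices never move.
3. **Division.**  Follower cells divide when their apical+basal edge
   elastic energy ``U_i = b (L_apical^2 + L_basal^2)/2`` stays above the
   threshold ``U_th`` for a latency ``S`` (stretch-triggered proliferation);
   notochord cells divide on an age clock with period ``D``.  Daughters are
   built from the midpoints of the apical and basal edges and restart with
   zero migration force.

The migration activity is graded along the axis:
``w_i = vmax ((x_i - x_min)/(x_max - x_min))^alpha`` over the cell-centroid
positions of the tissue.  The exponent controls the phenotype: a large
exponent confines migration to the posterior-most cell, a near-zero exponent
makes migration uniform, and exponent 1 gives the linear graded mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _kernels as _kern
from . import observables as obs
from .energy import ParamsLike, tissue_forces
from .mesh import (
    GeometryError,
    MechanicalParams,
    ParameterError,
    TissueMesh,
    cell_centroids_x,
)

#: exponents behind the named migration-gradient phenotypes
PRESET_EXPONENTS = {"posterior_only": 100.0, "uniform": 0.01, "graded": 1.0}


class IntegrationError(RuntimeError):
    """Vertex positions became non-finite (integration blow-up)."""


@dataclass(frozen=True)
class MigrationParams:
    """Graded-migration law: relaxation time, amplitude and gradient shape."""

    eta: float = 1.0
    vmax: float = 1.5
    exponent: float = 1.0
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ParameterError(f"eta must be > 0, got {self.eta}")
        if self.vmax < 0:
            raise ParameterError(f"vmax must be >= 0, got {self.vmax}")
        if self.exponent <= 0:
            raise ParameterError(f"exponent must be > 0, got {self.exponent}")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "MigrationParams":
        """Named phenotype: ``posterior_only``, ``uniform`` or ``graded``."""
        if name not in PRESET_EXPONENTS:
            raise ParameterError(
                f"unknown migration preset {name!r}; choose from {sorted(PRESET_EXPONENTS)}"
            )
        return cls(exponent=PRESET_EXPONENTS[name], preset=name, **overrides)


@dataclass(frozen=True)
class DivisionParams:
    """Stretch-triggered division: energy threshold, latency, latch policy.

    ``rearm_policy`` is ``"latch-and-recheck"`` (default: the cell must still
    exceed ``U_th`` when the latency expires; relaxing below the threshold
    clears the latch) or ``"latch-and-fire"`` (division fires once latched,
    regardless of later relaxation).
    """

    U_th: float = 0.15
    S_default: float = 6.0
    rearm_policy: str = "latch-and-recheck"

    def __post_init__(self) -> None:
        if self.U_th <= 0:
            raise ParameterError(f"U_th must be > 0, got {self.U_th}")
        if self.S_default < 0:
            raise ParameterError(f"S_default must be >= 0, got {self.S_default}")
        if self.rearm_policy not in ("latch-and-recheck", "latch-and-fire"):
            raise ParameterError(f"unknown rearm_policy {self.rearm_policy!r}")


@dataclass(frozen=True)
class ClockDivisionSpec:
    """Age-clock division with period ``D`` (daughters inherit the period).

    ``scope`` is ``"all"`` (every cell of the tissue carries the clock) or
    ``"posterior_most"`` (only the posterior-most cell divides — the
    moving-boundary abstraction of a progenitor pool adding cells at the
    growing tip, which elongates the tissue linearly at one cell width per
    period instead of doubling it).
    """

    D: float = 1.0
    scope: str = "all"

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ParameterError(f"D must be > 0, got {self.D}")
        if self.scope not in ("all", "posterior_most"):
            raise ParameterError(f"unknown clock scope {self.scope!r}")


@dataclass(frozen=True)
class IntegratorSpec:
    """Time step, seed and the noise-scaling convention of the integrator."""

    dt: float = 0.001
    seed: int = 0
    noise_convention: str = "sqrt_dt"  # increments (sigma/tau) sqrt(dt) N(0,1)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")


class CellStates:
    """Per-cell dynamic state as parallel arrays.

    ``v``: migration force; ``age``: time since birth; ``T_latch``: time the
    elastic energy first exceeded the division threshold (NaN = unset);
    ``D``: clock-division period (NaN for cells without a clock).
    """

    def __init__(self, n: int) -> None:
        self.v = np.zeros(n)
        self.age = np.zeros(n)
        self.T_latch = np.full(n, np.nan)
        self.D = np.full(n, np.nan)

    def __len__(self) -> int:
        return len(self.v)

    def copy(self) -> "CellStates":
        new = CellStates(0)
        for name in ("v", "age", "T_latch", "D"):
            setattr(new, name, getattr(self, name).copy())
        return new

    def append_daughter(self, parent: int) -> None:
        """Add one fresh daughter inheriting only the clock period."""
        self.v = np.append(self.v, 0.0)
        self.age = np.append(self.age, 0.0)
        self.T_latch = np.append(self.T_latch, np.nan)
        self.D = np.append(self.D, self.D[parent])

    def reset_as_daughter(self, i: int) -> None:
        self.v[i] = 0.0
        self.age[i] = 0.0
        self.T_latch[i] = np.nan


@dataclass
class SimState:
    """Mesh + per-cell states + current time of a running simulation."""

    mesh: TissueMesh
    states: CellStates
    t: float = 0.0

    def __post_init__(self) -> None:
        if len(self.states) != self.mesh.n_cells:
            raise ValueError("one CellState per cell required")
        if self.t < 0:
            raise ValueError("t must be >= 0")


# ----------------------------------------------------------------------
# migration


def migration_activity(centroid_xs: np.ndarray, params: MigrationParams) -> np.ndarray:
    """Graded migration activity ``w_i`` from cell-centroid positions.

    ``w_i = vmax ((x_i - x_min)/(x_max - x_min))^exponent``; the
    posterior-most centroid maps to ``vmax``, the anterior-most to 0.  When
    all centroids coincide (single cell), every cell gets ``vmax``.
    """
    xs = np.atleast_1d(np.asarray(centroid_xs, dtype=float))
    if xs.size == 0:
        raise ValueError("need at least one centroid")
    lo, hi = xs.min(), xs.max()
    if hi == lo:
        return np.full(xs.shape, params.vmax)
    s = (xs - lo) / (hi - lo)
    return params.vmax * s**params.exponent


def advance_migration_forces(
    v: np.ndarray, w: np.ndarray, eta: float, dt: float
) -> np.ndarray:
    """One classical RK4 step of ``eta dv/dt = -v + w`` with ``w`` frozen."""
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")

    def rhs(vv: np.ndarray) -> np.ndarray:
        return (w - vv) / eta

    k1 = rhs(v)
    k2 = rhs(v + 0.5 * dt * k1)
    k3 = rhs(v + 0.5 * dt * k2)
    k4 = rhs(v + dt * k3)
    return v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


# ----------------------------------------------------------------------
# vertex integration


def _per_vertex_tau_sigma(mesh: TissueMesh, params: ParamsLike) -> tuple[np.ndarray, np.ndarray]:
    n = mesh.n_vertices
    if isinstance(params, MechanicalParams):
        return np.full(n, params.tau), np.full(n, params.sigma)
    tau = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    for t in mesh.tissues:
        vids = np.unique(mesh.cells[mesh.cells_of(t)])
        tau[vids], sigma[vids] = params[t].tau, params[t].sigma
    # vertices not referenced by any cell (none in practice) default to the first tissue
    first = params[mesh.tissues[0]]
    tau = np.where(np.isnan(tau), first.tau, tau)
    sigma = np.where(np.isnan(sigma), first.sigma, sigma)
    return tau, sigma


def advance_vertices(
    mesh: TissueMesh,
    params: ParamsLike,
    integ: IntegratorSpec,
    rng: np.random.Generator,
    applied_forces: np.ndarray | None = None,
    t: float | None = None,
) -> None:
    """One Euler-Maruyama step; updates ``mesh.vertices`` in place.

    ``applied_forces`` (n, 2) are added to the mechanical forces (used for
    migration).  Fixed x-coordinates receive neither drift nor noise.
    Raises :class:`IntegrationError` if positions become non-finite.
    """
    forces = tissue_forces(mesh, params)
    if applied_forces is not None:
        if applied_forces.shape != mesh.vertices.shape:
            raise ValueError("applied_forces must align with the vertex table")
        forces = forces + applied_forces
    tau, sigma = _per_vertex_tau_sigma(mesh, params)
    dt = integ.dt
    incr = forces / tau[:, None] * dt
    if np.any(sigma > 0):
        incr += (sigma / tau)[:, None] * np.sqrt(dt) * rng.standard_normal(forces.shape)
    incr[mesh.fixed_x, 0] = 0.0
    mesh.vertices += incr
    if not np.all(np.isfinite(mesh.vertices)):
        stamp = f" at t={t:g}" if t is not None else ""
        raise IntegrationError(f"non-finite vertex positions{stamp}: integration blew up")


# ----------------------------------------------------------------------
# division rules


def strain_division_update(
    Ui: np.ndarray,
    t: float,
    T_latch: np.ndarray,
    params: DivisionParams,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Latch/fire logic of stretch-triggered division; mutates ``T_latch``.

    Latches ``T_latch = t`` at the first exceedance of ``U_th``; a cell is
    due once ``t > T_latch + S``.  Under the default latch-and-recheck
    policy, dropping below the threshold clears the latch, so only cells
    still above ``U_th`` at expiry divide.  Returns due cell ids ascending.
    """
    above = Ui > params.U_th
    if eligible is not None:
        cleared = eligible & ~above
        above = above & eligible
    else:
        cleared = ~above
    if params.rearm_policy == "latch-and-recheck":
        T_latch[cleared] = np.nan
    newly = above & np.isnan(T_latch)
    T_latch[newly] = t
    if params.rearm_policy == "latch-and-recheck":
        due = above & (t > T_latch + params.S_default)
    else:
        due = ~np.isnan(T_latch) & (t > T_latch + params.S_default)
    return np.flatnonzero(due)


def clock_division_update(
    age: np.ndarray, D: np.ndarray, eligible: np.ndarray | None = None
) -> np.ndarray:
    """Cells whose age reached their clock period ``D`` (ids ascending)."""
    due = age >= D
    if eligible is not None:
        due &= eligible
    return np.flatnonzero(due)


def divide_cell(mesh: TissueMesh, cell_id: int, states: CellStates) -> int:
    """Split one cell at the midpoints of its apical and basal edges.

    Two vertices are appended (basal midpoint, apical midpoint); the parent
    row is rewritten as the daughter on the first-basal-vertex side and the
    other daughter is appended.  Neighbors keep their vertices untouched;
    both daughters restart with zero migration force, age 0 and a cleared
    latch.  Returns the id of the appended daughter.
    """
    cid = mesh._check_cell_id(cell_id)
    v0, v1, v2, v3 = mesh.cells[cid]
    p = mesh.vertices
    if np.allclose(p[v0], p[v1]) or np.allclose(p[v2], p[v3]):
        raise GeometryError(f"cell {cid} has a degenerate apical or basal edge")
    mb = 0.5 * (p[v0] + p[v1])
    ma = 0.5 * (p[v2] + p[v3])
    i_mb = mesh.n_vertices
    i_ma = i_mb + 1
    mesh.vertices = np.vstack([mesh.vertices, mb[None], ma[None]])
    mesh.fixed_x = np.append(mesh.fixed_x, [False, False])
    mesh.cells[cid] = (v0, i_mb, i_ma, v3)
    mesh.cells = np.vstack([mesh.cells, [(i_mb, v1, v2, i_ma)]])
    mesh.cell_tissue = np.append(mesh.cell_tissue, mesh.cell_tissue[cid])
    states.append_daughter(cid)
    states.reset_as_daughter(cid)
    return mesh.n_cells - 1


# ----------------------------------------------------------------------
# simulation engine


@dataclass(frozen=True)
class TissueRole:
    """What drives one tissue: migration, strain division, and/or a clock."""

    migration: MigrationParams | None = None
    division: DivisionParams | None = None
    clock: ClockDivisionSpec | None = None


@dataclass(frozen=True)
class SingleTissueConfig:
    """Full parameter bundle for one follower-tissue run."""

    n_cells: int = 32
    cell_width: float = 1.0
    cell_height: float = 1.0
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    migration: MigrationParams = field(default_factory=MigrationParams)
    division: DivisionParams | None = field(default_factory=DivisionParams)
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    t_end: float = 100.0
    snapshot_every: float = 1.0
    tissue: str = "FP"


def _posterior_basal_slot(sign: np.ndarray) -> np.ndarray:
    """Cyclic-order slot of the posterior basal vertex, per cell.

    Positive-orientation storage puts the basal pair anterior-first for
    upright frames and posterior-first for mirrored ones.
    """
    return np.where(sign > 0, 1, 0)


class _EngineContext:
    """Per-cell/per-vertex arrays and work buffers; rebuilt after divisions."""

    PARAM_KEYS = ("a", "b", "c", "d", "V0", "h", "h_th", "ell")

    def __init__(self, mesh: TissueMesh, params: ParamsLike, roles: Mapping[str, TissueRole]):
        m, n = mesh.n_cells, mesh.n_vertices
        basal_y, sign = mesh.frame_arrays()
        self.cell_params = {"basal_y": basal_y, "sign": sign}
        if isinstance(params, MechanicalParams):
            for k in self.PARAM_KEYS:
                self.cell_params[k] = np.full(m, getattr(params, k))
            self.tau_v = np.full(n, params.tau)
            self.sigma_v = np.full(n, params.sigma)
        else:
            for k in self.PARAM_KEYS:
                self.cell_params[k] = np.empty(m)
            self.tau_v = np.empty(n)
            self.sigma_v = np.empty(n)
            self.tau_v[:] = self.sigma_v[:] = np.nan
            for t in mesh.tissues:
                sel = mesh.cell_tissue == t
                for k in self.PARAM_KEYS:
                    self.cell_params[k][sel] = getattr(params[t], k)
                vids = np.unique(mesh.cells[sel])
                self.tau_v[vids] = params[t].tau
                self.sigma_v[vids] = params[t].sigma
            first = params[mesh.tissues[0]]
            self.tau_v = np.where(np.isnan(self.tau_v), first.tau, self.tau_v)
            self.sigma_v = np.where(np.isnan(self.sigma_v), first.sigma, self.sigma_v)
        self.fixed_idx = np.flatnonzero(mesh.fixed_x)
        self.fixed_xs = mesh.vertices[self.fixed_idx, 0].copy()
        self.role_ids = {
            label: np.flatnonzero(mesh.cell_tissue == label) for label in roles
        }
        self.eligible = {}
        pb_slot = _posterior_basal_slot(sign)
        self.pb_verts = {}
        for label, ids in self.role_ids.items():
            mask = np.zeros(m, dtype=bool)
            mask[ids] = True
            self.eligible[label] = mask
            self.pb_verts[label] = mesh.cells[ids, pb_slot[ids]]
        self.forces = np.zeros((n, 2))
        self.basal_len = np.empty(m)
        self.apical_len = np.empty(m)
        self.cx = np.empty(m)
        self.drift_coef = 1.0 / self.tau_v[:, None]
        self.has_noise = bool(np.any(self.sigma_v > 0))

    def noise_coef(self, dt: float) -> np.ndarray:
        return (self.sigma_v / self.tau_v)[:, None] * np.sqrt(dt)

    def measure(self, mesh: TissueMesh) -> float:
        """Run the fused kernel; fills forces/lengths/centroids, returns min area."""
        return _kern.forces_and_measures(
            mesh.vertices,
            mesh.cells,
            self.cell_params,
            self.forces,
            self.basal_len,
            self.apical_len,
            self.cx,
        )


def simulate(
    state: SimState,
    params: ParamsLike,
    roles: Mapping[str, TissueRole],
    integ: IntegratorSpec,
    t_end: float,
    snapshot_every: float = 1.0,
    config_echo: dict | None = None,
    on_invalid_geometry: str = "raise",
) -> obs.SimulationTrace:
    """Advance a :class:`SimState` to ``t_end``, recording a trace.

    Per step: check both division rules against the current (post-update)
    geometry and split due cells (strain rule first, then clock; ties in
    ascending cell index), recompute migration activities from centroids
    (frozen within the step), RK4-advance the migration forces, then
    Euler-Maruyama-advance the vertices with each migratory cell's force
    applied at its posterior basal vertex.  Snapshots are recorded at
    ``snapshot_every`` cadence plus the final state; every division becomes
    a :class:`~midlinesim.observables.DivisionEvent`.  Identical seeds and
    configs give identical traces.

    A cell inverting (non-positive signed area) means the parameter regime
    left model validity; the run aborts with a diagnostic.  With
    ``on_invalid_geometry="raise"`` (default) that is a
    :class:`~midlinesim.mesh.GeometryError`; with ``"stop"`` the truncated
    trace is returned with the diagnostic in ``trace.aborted``.
    """
    if on_invalid_geometry not in ("raise", "stop"):
        raise ParameterError(f"unknown on_invalid_geometry {on_invalid_geometry!r}")
    mesh, states = state.mesh, state.states
    rng = np.random.default_rng(integ.seed)
    trace = obs.SimulationTrace(config_echo=config_echo or {}, seed=integ.seed)
    dt = integ.dt
    n_steps = int(round((t_end - state.t) / dt))
    snap_stride = max(1, int(round(snapshot_every / dt)))
    trace.frames.append((state.t, mesh.copy()))
    ctx = _EngineContext(mesh, params, roles)

    for step in range(n_steps + 1):
        min_area = ctx.measure(mesh)
        if min_area <= 0:
            msg = (
                f"cell inverted (non-positive area) at t={state.t:g}: "
                "parameter regime outside model validity"
            )
            if on_invalid_geometry == "raise":
                raise GeometryError(msg)
            trace.aborted = msg
            if trace.frames[-1][0] < state.t:
                trace.frames.append((state.t, mesh.copy()))
            break
        # divisions against the current geometry
        if _check_divisions(trace, mesh, states, roles, ctx, state.t):
            ctx = _EngineContext(mesh, params, roles)
            ctx.measure(mesh)
        if step == n_steps:
            break
        # migration targets and forces (activities frozen within the step)
        forces = ctx.forces
        for label, role in roles.items():
            if role.migration is None:
                continue
            ids = ctx.role_ids[label]
            w = migration_activity(ctx.cx[ids], role.migration)
            states.v[ids] = advance_migration_forces(states.v[ids], w, role.migration.eta, dt)
            np.add.at(forces[:, 0], ctx.pb_verts[label], states.v[ids])
        # Euler-Maruyama vertex update
        incr = forces * (dt * ctx.drift_coef)
        if ctx.has_noise:
            incr += ctx.noise_coef(dt) * rng.standard_normal(forces.shape)
        mesh.vertices += incr
        mesh.vertices[ctx.fixed_idx, 0] = ctx.fixed_xs
        state.t += dt
        states.age += dt
        if not np.all(np.isfinite(mesh.vertices)):
            raise IntegrationError(
                f"non-finite vertex positions at t={state.t:g}: integration blew up"
            )
        if (step + 1) % snap_stride == 0 or step + 1 == n_steps:
            trace.frames.append((state.t, mesh.copy()))
    return trace


def _check_divisions(
    trace: obs.SimulationTrace,
    mesh: TissueMesh,
    states: CellStates,
    roles: Mapping[str, TissueRole],
    ctx: "_EngineContext",
    t: float,
) -> bool:
    """Apply both division rules once; returns True if any cell divided."""
    due: list[int] = []
    for label, role in roles.items():
        ids = ctx.role_ids[label]
        eligible = ctx.eligible[label]
        if role.division is not None:
            Ui = 0.5 * ctx.cell_params["b"] * (ctx.basal_len**2 + ctx.apical_len**2)
            due.extend(strain_division_update(Ui, t, states.T_latch, role.division, eligible))
        if role.clock is not None:
            unset = np.isnan(states.D) & eligible
            states.D[unset] = role.clock.D
            clock_eligible = eligible
            if role.clock.scope == "posterior_most":
                clock_eligible = np.zeros(mesh.n_cells, dtype=bool)
                clock_eligible[ids[np.argmax(ctx.cx[ids])]] = True
            due.extend(clock_division_update(states.age, states.D, clock_eligible))
    for cid in sorted(set(due)):
        _record_division(trace, mesh, cid, t)
        divide_cell(mesh, cid, states)
    return bool(due)


def _b_coefficients(mesh: TissueMesh, params: ParamsLike) -> np.ndarray:
    if isinstance(params, MechanicalParams):
        return np.full(mesh.n_cells, params.b)
    out = np.empty(mesh.n_cells)
    for t in mesh.tissues:
        out[mesh.cell_tissue == t] = params[t].b
    return out


def _record_division(trace: obs.SimulationTrace, mesh: TissueMesh, cid: int, t: float) -> None:
    tissue = mesh.cell_tissue[cid]
    lo, hi = obs.tissue_extent(mesh, tissue)
    cx = float(cell_centroids_x(mesh)[cid])
    rel = 0.5 if hi == lo else min(1.0, max(0.0, (cx - lo) / (hi - lo)))
    trace.events.append(obs.DivisionEvent(t, tissue, cx, rel))


def run_single_tissue(
    config: SingleTissueConfig, on_invalid_geometry: str = "raise"
) -> obs.SimulationTrace:
    """Simulate one follower chain (migration + stretch-triggered division).

    Builds a fresh chain of ``n_cells`` identical quads (anterior pair
    x-anchored), then integrates to ``t_end``.
    """
    from .synthetic import make_initial_mesh

    mesh = make_initial_mesh(
        config.n_cells,
        cell_width=config.cell_width,
        cell_height=config.cell_height,
        h=config.mechanics.h,
        tissue=config.tissue,
    )
    state = SimState(mesh, CellStates(mesh.n_cells))
    roles = {config.tissue: TissueRole(migration=config.migration, division=config.division)}
    echo = {
        "n_cells": config.n_cells,
        "cell_width": config.cell_width,
        "cell_height": config.cell_height,
        "mechanics": vars(config.mechanics).copy(),
        "migration": vars(config.migration).copy(),
        "division": vars(config.division).copy() if config.division else None,
        "integrator": vars(config.integrator).copy(),
        "t_end": config.t_end,
        "tissue": config.tissue,
    }
    return simulate(
        state,
        config.mechanics,
        roles,
        config.integrator,
        config.t_end,
        config.snapshot_every,
        config_echo=echo,
        on_invalid_geometry=on_invalid_geometry,
    )
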