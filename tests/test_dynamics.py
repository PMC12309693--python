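"""Integrators, migration law, division rules, single-tissue runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import midlinesim as ms
from midlinesim.dynamics import (
    CellStates,
    advance_migration_forces,
    clock_division_update,
    divide_cell,
    migration_activity,
    strain_division_update,
)
from midlinesim.mesh import GeometryError, ParameterError


class TestMigrationActivity:
    def test_linear_gradient(self):
        w = migration_activity([0.0, 1.0, 2.0], ms.MigrationParams(vmax=1, exponent=1))
        np.testing.assert_allclose(w, [0.0, 0.5, 1.0])

    def test_power_law(self):
        w = migration_activity([0.0, 1.0, 2.0], ms.MigrationParams(vmax=1, exponent=2))
        np.testing.assert_allclose(w, [0.0, 0.25, 1.0])

    def test_degenerate_range_gives_vmax(self):
        w = migration_activity([3.0], ms.MigrationParams(vmax=0.7))
        np.testing.assert_allclose(w, [0.7])
        w = migration_activity([2.0, 2.0], ms.MigrationParams(vmax=0.7))
        np.testing.assert_allclose(w, [0.7, 0.7])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            migration_activity([], ms.MigrationParams())

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True),
        st.floats(0.05, 10.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_monotone_in_position_and_bounded(self, xs, exponent):
        params = ms.MigrationParams(vmax=2.0, exponent=exponent)
        xs = sorted(xs)
        w = migration_activity(xs, params)
        assert np.all(np.diff(w) >= -1e-12)
        assert np.all((w >= 0) & (w <= params.vmax + 1e-12))
        assert w[-1] == pytest.approx(params.vmax)
        assert w[0] == pytest.approx(0.0, abs=1e-12)

    def test_preset_names_map_to_phenotype_exponents(self):
        assert ms.MigrationParams.from_preset("posterior_only").exponent == 100.0
        assert ms.MigrationParams.from_preset("uniform").exponent == 0.01
        assert ms.MigrationParams.from_preset("graded").exponent == 1.0
        with pytest.raises(ParameterError):
            ms.MigrationParams.from_preset("sideways")


class TestMigrationForceODE:
    def test_fixed_point(self):
        v = advance_migration_forces(np.zeros(3), np.zeros(3), eta=1.0, dt=0.01)
        np.testing.assert_array_equal(v, 0.0)

    def test_matches_closed_form_relaxation(self):
        """RK4 reproduces v(t) = w (1 - exp(-t/eta)) to 1e-6 at t = 1."""
        v = np.array([0.0])
        for _ in range(1000):
            v = advance_migration_forces(v, np.array([1.0]), eta=1.0, dt=0.001)
        assert v[0] == pytest.approx(1 - np.exp(-1), abs=1e-6)

    def test_step_halving_changes_little(self):
        """4th-order accuracy: halving dt shifts the t=1 answer below 1e-8."""
        results = []
        for dt in (0.002, 0.001):
            v = np.array([0.0])
            for _ in range(int(round(1.0 / dt))):
                v = advance_migration_forces(v, np.array([1.0]), eta=1.0, dt=dt)
            results.append(v[0])
        assert abs(results[1] - results[0]) < 1e-8


class TestVertexIntegration:
    def test_no_force_no_noise_no_motion(self, chain8):
        p = ms.MechanicalParams(a=0, b=0, c=0, d=0, sigma=0.0)
        before = chain8.vertices.copy()
        ms.advance_vertices(chain8, p, ms.IntegratorSpec(), np.random.default_rng(0))
        np.testing.assert_array_equal(chain8.vertices, before)

    def test_deterministic_euler_step(self, chain8):
        """A constant applied force (tau, 0) advances x by exactly dt."""
        p = ms.MechanicalParams(a=0, b=0, c=0, d=0, sigma=0.0, tau=2.0)
        applied = np.zeros_like(chain8.vertices)
        j = 10  # a free vertex
        applied[j, 0] = p.tau
        before = chain8.vertices.copy()
        ms.advance_vertices(chain8, p, ms.IntegratorSpec(dt=0.001), np.random.default_rng(0), applied)
        assert chain8.vertices[j, 0] - before[j, 0] == pytest.approx(0.001)
        assert chain8.vertices[j, 1] == before[j, 1]

    def test_fixed_x_never_moves_under_force(self, chain8):
        p = ms.MechanicalParams(a=0, b=0, c=0, d=0, sigma=0.0)
        applied = np.ones_like(chain8.vertices)  # push everything
        before = chain8.vertices.copy()
        ms.advance_vertices(chain8, p, ms.IntegratorSpec(), np.random.default_rng(0), applied)
        np.testing.assert_array_equal(
            chain8.vertices[chain8.fixed_x, 0], before[chain8.fixed_x, 0]
        )

    def test_driftless_variance_law(self):
        """Var of free coordinates after time t is (sigma/tau)^2 t within 3 SE."""
        mesh = ms.make_initial_mesh(2499)  # 5000 vertices -> ~1e4 free coords
        p = ms.MechanicalParams(a=0, b=0, c=0, d=0, sigma=0.05, tau=2.0)
        integ = ms.IntegratorSpec(dt=0.001)
        rng = np.random.default_rng(123)
        start = mesh.vertices.copy()
        k = 100
        for _ in range(k):
            ms.advance_vertices(mesh, p, integ, rng)
        t = k * integ.dt
        disp = (mesh.vertices - start)[~mesh.fixed_x].ravel()
        expected = (p.sigma / p.tau) ** 2 * t
        se = expected * np.sqrt(2.0 / (disp.size - 1))
        assert abs(disp.var() - expected) < 3 * se

    def test_blowup_detected(self, chain8):
        chain8.vertices[5] = np.nan
        p = ms.MechanicalParams()
        with pytest.raises((ms.IntegrationError, FloatingPointError, ValueError)):
            with np.errstate(invalid="raise"):
                ms.advance_vertices(chain8, p, ms.IntegratorSpec(), np.random.default_rng(0))


class TestStrainDivisionRule:
    def scripted(self, Ui_series, params, dt=0.1):
        """Run the latch over a scripted per-step Ui trajectory of one cell."""
        T_latch = np.array([np.nan])
        fired = []
        for k, u in enumerate(Ui_series):
            t = k * dt
            due = strain_division_update(np.array([u]), t, T_latch, params)
            if due.size:
                fired.append(t)
                T_latch[:] = np.nan
        return fired

    def test_never_exceeding_never_divides(self):
        p = ms.DivisionParams(U_th=1.0, S_default=0.2)
        assert self.scripted([0.5] * 50, p) == []

    def test_fires_after_latency(self):
        """Exceeds at t=2.0 with S=0.5: fires at the first step with t > 2.5."""
        p = ms.DivisionParams(U_th=1.0, S_default=0.5)
        series = [0.0] * 20 + [2.0] * 40  # exceeds from t = 2.0
        fired = self.scripted(series, p, dt=0.1)
        assert fired[0] == pytest.approx(2.6)

    def test_relaxed_cell_not_divided_under_recheck(self):
        """Dropping below threshold before the latency expires clears the latch."""
        p = ms.DivisionParams(U_th=1.0, S_default=0.5)
        series = [0.0] * 20 + [2.0] * 3 + [0.5] * 40
        assert self.scripted(series, p, dt=0.1) == []

    def test_latch_and_fire_divides_anyway(self):
        p = ms.DivisionParams(U_th=1.0, S_default=0.5, rearm_policy="latch-and-fire")
        series = [0.0] * 20 + [2.0] * 3 + [0.5] * 40
        fired = self.scripted(series, p, dt=0.1)
        assert fired and fired[0] == pytest.approx(2.6)

    def test_eligibility_mask_scopes_latch(self):
        p = ms.DivisionParams(U_th=1.0, S_default=0.0)
        T_latch = np.array([0.0, 0.0])  # both latched earlier at t=0
        eligible = np.array([True, False])
        due = strain_division_update(np.array([2.0, 2.0]), 1.0, T_latch, p, eligible)
        assert due.tolist() == [0]
        assert T_latch[1] == pytest.approx(0.0)  # other tissue's latch untouched


class TestClockDivision:
    def test_due_at_period(self):
        due = clock_division_update(np.array([0.5, 0.8, 1.0]), np.array([0.8, 0.8, 0.8]))
        assert due.tolist() == [1, 2]

    def test_simultaneous_divisions_double_count(self):
        mesh = ms.make_initial_mesh(4)
        states = CellStates(4)
        states.age[:] = 1.0
        states.D[:] = 0.8
        for cid in clock_division_update(states.age, states.D):
            divide_cell(mesh, cid, states)
        assert mesh.n_cells == 8

    def test_run_shorter_than_period_never_divides(self):
        mesh = ms.make_initial_mesh(4, tissue="noto")
        state = ms.SimState(mesh, CellStates(4))
        roles = {"noto": ms.TissueRole(clock=ms.ClockDivisionSpec(D=1.2))}
        trace = ms.simulate(state, ms.MechanicalParams(sigma=0), roles, ms.IntegratorSpec(), t_end=1.0)
        assert len(trace.events) == 0

    def test_first_division_at_period(self):
        mesh = ms.make_initial_mesh(4, tissue="noto")
        state = ms.SimState(mesh, CellStates(4))
        roles = {"noto": ms.TissueRole(clock=ms.ClockDivisionSpec(D=0.8, scope="posterior_most"))}
        trace = ms.simulate(state, ms.MechanicalParams(sigma=0), roles, ms.IntegratorSpec(), t_end=1.0)
        assert len(trace.events) == 1
        assert trace.events[0].t == pytest.approx(0.8, abs=1e-9)
        assert trace.events[0].relative_position > 0.7


class TestDivideCell:
    def test_unit_square_daughters(self, unit_square_mesh):
        states = CellStates(1)
        new_id = divide_cell(unit_square_mesh, 0, states)
        mesh = unit_square_mesh
        assert mesh.n_cells == 2 and mesh.n_vertices == 6
        areas = [ms.cell_area(mesh, i) for i in range(2)]
        assert areas == pytest.approx([0.5, 0.5])
        assert sum(areas) == pytest.approx(1.0)
        # new vertices at the exact edge midpoints
        np.testing.assert_allclose(mesh.vertices[4], [0.5, 0.0])
        np.testing.assert_allclose(mesh.vertices[5], [0.5, 1.0])
        assert new_id == 1

    def test_neighbors_keep_vertices_bit_identical(self):
        mesh = ms.make_initial_mesh(3)
        states = CellStates(3)
        before = mesh.vertices.copy()
        divide_cell(mesh, 1, states)
        assert mesh.n_cells == 4
        np.testing.assert_array_equal(mesh.vertices[: len(before)], before)

    def test_daughter_state_reset(self):
        mesh = ms.make_initial_mesh(2)
        states = CellStates(2)
        states.v[:] = 3.0
        states.age[:] = 5.0
        states.T_latch[0] = 1.0
        new_id = divide_cell(mesh, 0, states)
        for i in (0, new_id):
            assert states.v[i] == 0.0
            assert states.age[i] == 0.0
            assert np.isnan(states.T_latch[i])
        assert states.v[1] == 3.0  # untouched neighbor

    def test_degenerate_edge_rejected(self, unit_square_mesh):
        unit_square_mesh.vertices[1] = unit_square_mesh.vertices[0]
        with pytest.raises(GeometryError):
            divide_cell(unit_square_mesh, 0, CellStates(1))


class TestRunSingleTissue:
    def test_quiescent_run_preserves_length(self):
        cfg = ms.SingleTissueConfig(
            n_cells=6,
            mechanics=ms.MechanicalParams(sigma=0.0),
            migration=ms.MigrationParams(vmax=0.0),
            t_end=2.0,
        )
        trace = ms.run_single_tissue(cfg)
        assert len(trace.events) == 0
        first = ms.tissue_length(trace.frames[0][1], "FP")
        last = ms.tissue_length(trace.final_mesh, "FP")
        # relaxation shrinks slightly; no elongation without migration/division
        assert last <= first + 1e-9

    def test_initial_vertex_count(self):
        cfg = ms.SingleTissueConfig(n_cells=32, t_end=0.01)
        trace = ms.run_single_tissue(cfg)
        assert trace.frames[0][1].n_vertices == 66  # (m + 1) * 2
        assert trace.frames[0][1].n_cells == 32

    def test_identical_seed_identical_trace(self):
        cfgs = [
            ms.SingleTissueConfig(n_cells=6, t_end=1.0, integrator=ms.IntegratorSpec(seed=9))
            for _ in range(2)
        ]
        t1, t2 = (ms.run_single_tissue(c) for c in cfgs)
        np.testing.assert_array_equal(t1.final_mesh.vertices, t2.final_mesh.vertices)
        assert [e.t for e in t1.events] == [e.t for e in t2.events]

    def test_different_seed_different_trace(self):
        t1 = ms.run_single_tissue(ms.SingleTissueConfig(n_cells=6, t_end=0.5))
        t2 = ms.run_single_tissue(
            ms.SingleTissueConfig(n_cells=6, t_end=0.5, integrator=ms.IntegratorSpec(seed=1))
        )
        assert not np.array_equal(t1.final_mesh.vertices, t2.final_mesh.vertices)
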