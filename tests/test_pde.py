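import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemcell import chemistry, io, pde
from chemcell.mesh import DomainField, build_rectangular_mesh
from chemcell.pde import (BoundaryConditionSpec, FieldState, SolverSettings,
                          assemble_operators, run_simulation, step)


def _operators(nx, ny, h, d, bc_kind="neumann_flux", bc_value=0.0):
    mesh = build_rectangular_mesh(nx, ny, h)
    field = DomainField(
        label_grid=np.array([["D"]], dtype=object), key={"D": "Domain"},
        diffusivity={("u", "Domain"): d},
        boundary_conditions={"u": BoundaryConditionSpec("u", bc_kind,
                                                        bc_value)})
    return mesh, assemble_operators(mesh, field, ["u"])


class TestOperators:
    def test_zero_diffusivity_gives_zero_stiffness(self):
        _, ops = _operators(4, 4, 1.0, 0.0)
        assert ops.stiffness["u"].nnz == 0

    def test_stiffness_row_sums_vanish(self):
        _, ops = _operators(5, 4, 0.8, 2.5)
        rows = np.asarray(ops.stiffness["u"].sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 0.0, atol=1e-12)

    def test_unit_right_triangle_element_matrix(self):
        # analytic P1 stiffness of the triangle (0,0),(1,0),(1,1) with D=1:
        # grad phi are (-1,0), (1,-1), (0,1) -> K = [[.5,-.5,0],
        # [-.5,1,-.5],[0,-.5,.5]]
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        K = pde._element_stiffness(xy)
        expected = np.array([[0.5, -0.5, 0.0],
                             [-0.5, 1.0, -0.5],
                             [0.0, -0.5, 0.5]])
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_missing_diffusivity_names_species_and_subdomain(self):
        mesh = build_rectangular_mesh(2, 2, 1.0)
        field = DomainField(label_grid=np.array([["D"]], dtype=object),
                            key={"D": "Domain"}, diffusivity={})
        with pytest.raises(KeyError, match="'u'.*'Domain'"):
            assemble_operators(mesh, field, ["u"])


class TestStepping:
    def test_uniform_field_is_a_fixed_point_of_diffusion(self):
        _, ops = _operators(6, 6, 1.0, 3.0)
        settings = SolverSettings(dt=0.1, t_end=1.0)
        state = FieldState(0.0, np.full((ops.mesh.n_nodes, 1), 2.5))
        new = step(state, ops, [], settings)
        np.testing.assert_allclose(new.values, 2.5, atol=1e-12)

    def test_zero_flux_diffusion_conserves_lumped_mass(self):
        mesh, ops = _operators(8, 8, 1.0, 2.0)
        rng = np.random.default_rng(3)
        state = FieldState(0.0, rng.uniform(0, 1, (mesh.n_nodes, 1)))
        total0 = float(ops.mass @ state.values[:, 0])
        settings = SolverSettings(dt=0.05, t_end=1.0)
        for _ in range(50):
            state = step(state, ops, [], settings)
            assert ops.mass @ state.values[:, 0] == \
                pytest.approx(total0, rel=1e-10)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_implicit_diffusion_obeys_the_maximum_principle(self, seed):
        mesh, ops = _operators(6, 5, 1.0, 1.7)
        rng = np.random.default_rng(seed)
        state = FieldState(0.0, rng.uniform(0, 5, (mesh.n_nodes, 1)))
        lo, hi = state.values.min(), state.values.max()
        new = step(state, ops, [], SolverSettings(dt=0.5, t_end=1.0))
        assert new.values.min() >= lo - 1e-10
        assert new.values.max() <= hi + 1e-10

    def test_cosine_mode_decay_converges_at_second_order(self):
        # u(x,0)=cos(pi x / L) satisfies zero-flux BCs and decays as
        # exp(-D (pi/L)^2 t); refine h and dt ~ h^2 together
        L, D, t_end = 4.0, 1.0, 0.5
        errors = []
        for h, dt in [(0.5, 0.02), (0.25, 0.005)]:
            nx = int(L / h)
            mesh, ops = _operators(nx, 1, h, D)
            x = mesh.node_xy[:, 0]
            state = FieldState(0.0, (1.0 + np.cos(np.pi * x / L))[:, None])
            settings = SolverSettings(dt=dt, t_end=t_end)
            for _ in range(int(round(t_end / dt))):
                state = step(state, ops, [], settings)
            exact = 1.0 + np.cos(np.pi * x / L) * np.exp(
                -D * (np.pi / L) ** 2 * t_end)
            errors.append(np.sqrt(np.mean((state.values[:, 0] - exact) ** 2)))
        order = np.log2(errors[0] / errors[1])
        assert order >= 1.8

    def test_homogeneous_reaction_steady_state_is_scheme_fixed_point(
            self, schnakenberg_patterning):
        mesh, _ = _operators(5, 5, 1.0, 1.0)
        field = DomainField(
            label_grid=np.array([["D"]], dtype=object), key={"D": "Domain"},
            diffusivity={("U", "Domain"): 1.0, ("V", "Domain"): 40.0},
            boundary_conditions={
                "U": BoundaryConditionSpec("U", "neumann_flux", 0.0),
                "V": BoundaryConditionSpec("V", "neumann_flux", 0.0)})
        ops = assemble_operators(mesh, field, ["U", "V"])
        node_systems = [(schnakenberg_patterning,
                         np.arange(mesh.n_nodes), np.array([0, 1]))]
        state = FieldState(0.0, np.tile([1.0, 0.9], (mesh.n_nodes, 1)))
        new = step(state, ops, node_systems, SolverSettings(dt=0.05,
                                                            t_end=1.0))
        np.testing.assert_allclose(new.values, state.values, atol=1e-9)

    def test_nonzero_neumann_injects_flux_times_perimeter(self):
        h, flux = 0.5, 0.3
        mesh, ops = _operators(8, 4, h, 1.0, bc_kind="neumann_flux",
                               bc_value=flux)
        state = FieldState(0.0, np.zeros((mesh.n_nodes, 1)))
        dt = 0.1
        new = step(state, ops, [], SolverSettings(dt=dt, t_end=1.0))
        perimeter = 2 * (8 + 4) * h
        added = ops.mass @ new.values[:, 0]
        assert added == pytest.approx(flux * perimeter * dt, rel=1e-10)

    def test_dirichlet_boundary_pins_values(self):
        mesh, ops = _operators(5, 5, 1.0, 1.0, bc_kind="dirichlet_value",
                               bc_value=2.0)
        state = FieldState(0.0, np.zeros((mesh.n_nodes, 1)))
        settings = SolverSettings(dt=0.1, t_end=1.0)
        for _ in range(5):
            state = step(state, ops, [], settings)
        boundary = state.values[mesh.on_boundary, 0]
        np.testing.assert_allclose(boundary, 2.0, atol=1e-12)
        # diffusion pulls the interior up toward the boundary value
        assert state.values[~mesh.on_boundary, 0].min() > 0

    def test_periodic_boundary_identifies_opposite_edges(self):
        mesh, ops = _operators(6, 6, 1.0, 1.0, bc_kind="periodic")
        rng = np.random.default_rng(1)
        u = rng.uniform(0, 1, (mesh.n_nodes, 1))
        state = step(FieldState(0.0, u), ops, [],
                     SolverSettings(dt=0.2, t_end=1.0))
        left = [mesh.node_index(0, j) for j in range(7)]
        right = [mesh.node_index(6, j) for j in range(7)]
        np.testing.assert_allclose(state.values[left, 0],
                                   state.values[right, 0], atol=1e-12)


class TestRunSimulation:
    def test_domain_only_run_has_no_cell_records(self, tmp_path):
        config = io.write_exemplar("schnakenberg_pattern", tmp_path)
        model = io.load_model(config, overrides={
            "domain_dimensions": "8, 8", "end_time": 1.0, "time_step": 0.05,
            "sampling_rate": 0.5})
        traj = run_simulation(model)
        assert traj.cell_records == []
        assert len(traj.times) == 3

    def test_fisher_front_moves_monotonically_right(self, tmp_path):
        config = io.write_exemplar("fisher_kpp", tmp_path)
        # shrink the domain but keep the seeded strip one unit wide
        (tmp_path / "DomainTopology.csv").write_text(
            ",".join(["S"] + ["B"] * 29) + "\n")
        model = io.load_model(config, overrides={
            "domain_dimensions": "30, 2", "end_time": 8.0,
            "element_dimension": "0.5", "time_step": 0.02,
            "sampling_rate": 1.0})
        traj = run_simulation(model)
        x, profiles = traj.slice_values(0)
        fronts = []
        for u in profiles[1:]:        # skip the initial relaxation sample
            crossing = np.argmax(u < 0.5)
            fronts.append(x[crossing])
        assert all(b >= a for a, b in zip(fronts, fronts[1:]))

    def test_fixed_seed_reproduces_the_trajectory_bitwise(self, tmp_path):
        config = io.write_exemplar("schnakenberg_pattern", tmp_path)
        overrides = {"domain_dimensions": "10, 10", "end_time": 2.0,
                     "time_step": 0.05, "sampling_rate": 1.0, "rng_seed": 5}
        t1 = run_simulation(io.load_model(config, overrides=overrides))
        t2 = run_simulation(io.load_model(config, overrides=overrides))
        for a, b in zip(t1.fields, t2.fields):
            assert np.array_equal(a, b)

    def test_solver_failure_reports_time(self):
        # explosive cubic growth with a large explicit step goes non-finite
        system = chemistry.ReactionSystem(["U"], [
            chemistry.parse_reaction_line(
                "MassActionReaction: 3 U -> 4 U ; k = 100")])
        mesh, ops = _operators(3, 3, 1.0, 0.0)
        state = FieldState(0.0, np.full((mesh.n_nodes, 1), 10.0))
        node_systems = [(system, np.arange(mesh.n_nodes), np.array([0]))]
        settings = SolverSettings(dt=0.5, t_end=1.0)
        with pytest.raises(chemistry.SolverFailure), \
                np.errstate(over="ignore", invalid="ignore"):
            for _ in range(20):
                state = step(state, ops, node_systems, settings)
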