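import numpy as np
import pytest

from alveomech.fem import (LoadCase, SolverError, solve_linear, solve_newton,
                           displacement_at, structured_rectangle)
from alveomech.geometry import build_outline, generate_mesh, PhenotypeParams
from alveomech.materials import (MaterialCard, LinearElastic, OgdenParams,
                                 default_material_set)
from alveomech.scenarios import make_scenario, build_load_case


def _beam(nx=100, ny=10, crossed=True):
    return structured_rectangle(10.0, 1.0, nx, ny, region="BEAM",
                                crossed=crossed)


def _clamped_tip_load(mesh, P=1.0):
    left = mesh.node_sets["LEFT"]
    right = mesh.node_sets["RIGHT"]
    dirichlet = [(int(n), (0, 1), (0.0, 0.0)) for n in left]
    loads = [(int(n), np.array([0.0, -P / len(right)])) for n in right]
    return LoadCase(point_loads=loads, dirichlet=dirichlet)


class TestLoadCase:
    def test_rigid_modes_guard(self):
        with pytest.raises(SolverError, match="rigid"):
            LoadCase(point_loads=[], dirichlet=[(0, (0,), (0.0,))])

    def test_load_factor_range(self):
        with pytest.raises(SolverError):
            LoadCase(dirichlet=[(0, (0, 1), (0, 0)), (1, (1,), (0,))],
                     load_factor=1.5)


class TestLinearSolve:
    def test_zero_load_zero_solution(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        load = LoadCase(point_loads=[], dirichlet=load.dirichlet)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        assert np.allclose(sol.node_displacements, 0.0)
        assert np.allclose(sol.element_stress, 0.0)
        assert sol.converged and sol.iterations == 1

    def test_patch_test_exact(self):
        """Boundary-imposed linear displacement reproduces the uniform strain
        field exactly (constant-strain triangles)."""
        mesh = structured_rectangle(1.0, 1.0, 4, 4, region="B")
        a, b, c = 0.3, 0.2, -0.1
        exact = np.column_stack([
            a * mesh.nodes[:, 0] + c * mesh.nodes[:, 1],
            b * mesh.nodes[:, 1] + c * mesh.nodes[:, 0]])
        dirichlet = [(int(n), (0, 1), tuple(exact[n]))
                     for n in mesh.node_sets["BOUNDARY"]]
        mats = MaterialCard(materials={"B": LinearElastic(E=7.0, nu=0.3)})
        sol = solve_linear(mesh, mats, LoadCase(point_loads=[],
                                                dirichlet=dirichlet))
        assert np.abs(sol.node_displacements - exact).max() < 1e-12
        # interior strain constant -> identical stress in every element
        assert np.ptp(sol.element_stress, axis=0).max() < 1e-12

    def test_cantilever_vs_beam_theory(self):
        """Tip deflection within 2% of the Euler-Bernoulli + shear
        (Timoshenko) closed form at 0.1 mm mesh size."""
        E, nu, P, L, H = 1000.0, 0.0, 1.0, 10.0, 1.0
        mesh = _beam()
        mats = MaterialCard(materials={"BEAM": LinearElastic(E=E, nu=nu)})
        sol = solve_linear(mesh, mats, _clamped_tip_load(mesh, P))
        tip = sol.node_displacements[mesh.node_sets["RIGHT"], 1].mean()
        I = H ** 3 / 12.0
        ref = -(P * L ** 3 / (3 * E * I) + P * L / ((5 / 6) * (E / 2) * H))
        assert tip == pytest.approx(ref, rel=0.02)

    def test_global_equilibrium(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        total = sol.reactions.sum(axis=0) + sol.external_force.reshape(-1, 2).sum(axis=0)
        assert np.abs(total).max() < 1e-8

    def test_linearity_in_load(self, coarse_mesh):
        spec1 = make_scenario("CONVENTIONAL", crown_force=1.0)
        spec2 = make_scenario("CONVENTIONAL", crown_force=2.0)
        mats = default_material_set()
        s1 = solve_linear(coarse_mesh, mats, build_load_case(spec1, coarse_mesh))
        s2 = solve_linear(coarse_mesh, mats, build_load_case(spec2, coarse_mesh))
        ref = np.abs(s2.node_displacements).max()
        assert np.abs(s2.node_displacements
                      - 2.0 * s1.node_displacements).max() < 1e-10 * ref

    def test_energy_positive(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        assert sol.strain_energy() > 0

    def test_mirror_symmetry_oracle(self):
        """Mirrored phenotype + mirrored load gives the mirrored field to
        1e-9 mm."""
        params = PhenotypeParams()
        mesh = generate_mesh(build_outline(params), 0.2, 1.0)
        mesh_m = generate_mesh(build_outline(params.mirrored()), 0.2, 1.0)
        index_m = {(float(x), float(y)): i
                   for i, (x, y) in enumerate(mesh_m.nodes)}
        mats = default_material_set()
        bracket = mesh.nodes[mesh.node_sets["CROWN_LOAD"][0]]
        load = LoadCase(
            point_loads=[(int(mesh.node_sets["CROWN_LOAD"][0]),
                          np.array([1.0, 0.0]))],
            dirichlet=[(int(n), (0, 1), (0.0, 0.0))
                       for n in mesh.node_sets["FIXED_BOUNDARY"]])
        # mirrored load: -x force at the mirrored bracket node
        nb = index_m[(float(-bracket[0]), float(bracket[1]))]
        load_m = LoadCase(
            point_loads=[(nb, np.array([-1.0, 0.0]))],
            dirichlet=[(int(n), (0, 1), (0.0, 0.0))
                       for n in mesh_m.node_sets["FIXED_BOUNDARY"]])
        u = solve_linear(mesh, mats, load).node_displacements
        um = solve_linear(mesh_m, mats, load_m).node_displacements
        for i, (x, y) in enumerate(mesh.nodes):
            j = index_m[(float(-x), float(y))]
            assert abs(u[i, 0] + um[j, 0]) < 1e-9
            assert abs(u[i, 1] - um[j, 1]) < 1e-9

    def test_mesh_convergence_crown_displacement(self, comparison_by_key):
        """Crown displacement changes < 2% from the default mesh to h/2."""
        from alveomech.scenarios import run_scenario
        r = comparison_by_key[("CONVENTIONAL", 12500.0)]
        fine = run_scenario(PhenotypeParams(), make_scenario("CONVENTIONAL"),
                            12500.0, h_pdl=0.05, h_far=0.25)
        c0 = r.summary.crown_disp_x
        c1 = fine.summary.crown_disp_x
        assert abs(c1 - c0) / abs(c1) < 0.02

    def test_singular_system_raises(self):
        mesh = structured_rectangle(1.0, 1.0, 2, 2, region="B")
        mats = MaterialCard(materials={"B": LinearElastic(E=1.0, nu=0.3)})
        # three constrained dofs all on one node: rotation remains free
        load = LoadCase(point_loads=[(8, (0.0, 1.0))],
                        dirichlet=[(0, (0, 1), (0.0, 0.0)),
                                   (0, (0,), (0.0,))])
        with pytest.raises(SolverError):
            solve_linear(mesh, mats, load)


class TestDisplacementAt:
    def test_micron_conversion(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        node = int(coarse_mesh.node_sets["CROWN_LOAD"][0])
        assert displacement_at(sol, node) == pytest.approx(
            1000.0 * sol.node_displacements[node])

    def test_fixed_node_zero(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        fixed = int(coarse_mesh.node_sets["FIXED_BOUNDARY"][0])
        assert np.allclose(displacement_at(sol, fixed), 0.0)

    def test_out_of_range(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_linear(coarse_mesh, default_material_set(), load)
        with pytest.raises(IndexError):
            displacement_at(sol, coarse_mesh.n_nodes)


class TestNewton:
    def test_requires_ogden(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        with pytest.raises(SolverError, match="ogden"):
            solve_newton(coarse_mesh, default_material_set(), load)

    def test_zero_load(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        load = LoadCase(point_loads=load.point_loads, dirichlet=load.dirichlet,
                        load_factor=0.0)
        sol = solve_newton(coarse_mesh, default_material_set(pdl_model="ogden"),
                           load, steps=1)
        assert sol.converged
        assert np.allclose(sol.node_displacements, 0.0)

    def test_small_load_matches_linearized_pdl(self, coarse_mesh):
        """At 0.01 N the hyperelastic path agrees with the linear solver
        using the consistent linearization of the Ogden law (2%)."""
        og = OgdenParams()
        K, mu = og.bulk, og.mu
        lin = default_material_set()
        lin = MaterialCard(materials={
            **lin.materials,
            "PDL": LinearElastic(E=9 * K * mu / (3 * K + mu),
                                 nu=(3 * K - 2 * mu) / (6 * K + 2 * mu))})
        load = build_load_case(make_scenario("CONVENTIONAL", crown_force=0.01),
                               coarse_mesh)
        sl = solve_linear(coarse_mesh, lin, load)
        sn = solve_newton(coarse_mesh,
                          default_material_set(pdl_model="ogden"),
                          load, steps=2)
        assert sn.converged
        node = int(coarse_mesh.node_sets["CROWN_LOAD"][0])
        a = displacement_at(sl, node)[0]
        b = displacement_at(sn, node)[0]
        assert b == pytest.approx(a, rel=0.02)

    def test_full_load_converges_quickly(self, coarse_mesh):
        load = build_load_case(make_scenario("CONVENTIONAL"), coarse_mesh)
        sol = solve_newton(coarse_mesh, default_material_set(pdl_model="ogden"),
                           load, steps=5)
        assert sol.converged
        assert sol.iterations <= 20
        assert sol.residual_norm < 1e-8

    def test_nonconvergence_is_honest(self, coarse_mesh):
        spec = make_scenario("CONVENTIONAL", crown_force=50.0)
        load = build_load_case(spec, coarse_mesh)
        sol = solve_newton(coarse_mesh, default_material_set(pdl_model="ogden"),
                           load, steps=1, max_iter=1)
        assert not sol.converged
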