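import numpy as np
import pytest

from ionfv import (
    BoundaryData,
    ModelParams,
    State,
    build_rectangular_mesh,
    convergence_order,
    discrete_entropy,
    discrete_gradient,
    discrete_h1_norm,
    entropy_inequality_series,
    entropy_production,
    l1_error,
    refine_mesh,
    relative_entropy,
)
from ionfv.cases import random_admissible_state
from ionfv.diagnostics import bounds_and_mass_report
from ionfv.mesh import ancestor_indices
from ionfv.solver import SolverConfig, run_transient

from conftest import drift_free_params, two_cell_state


class TestEntropy:
    def test_half_filled_unit_cell(self, single_cell_mesh):
        # h(z) = z log z - z + 1; u1 = u0 = 0.5 -> H = 2 h(0.5) = 1 - log 2
        s = State(np.array([[0.5]]), np.zeros(1))
        H = discrete_entropy(s, single_cell_mesh)
        assert H == pytest.approx(1.0 - np.log(2.0))

    def test_degenerate_cell_uses_h0_equals_one(self, single_cell_mesh):
        # u1 = 1, u0 = 0: H = h(1) + h(0) = 0 + 1
        s = State(np.array([[1.0]]), np.zeros(1))
        assert discrete_entropy(s, single_cell_mesh) == pytest.approx(1.0)

    def test_uniform_mixture_closed_form(self):
        mesh = build_rectangular_mesh(3, 3, domain=((0, 0), (2, 1)))
        n = 3
        s = State(np.full((n, mesh.n_cells), 1.0 / (n + 1)), np.zeros(mesh.n_cells))
        expected = 2.0 * (n - np.log(n + 1))  # area A = 2
        assert discrete_entropy(s, mesh) == pytest.approx(expected)

    def test_negative_concentration_rejected(self, single_cell_mesh):
        s = State(np.array([[-1e-6]]), np.zeros(1))
        with pytest.raises(ValueError):
            discrete_entropy(s, single_cell_mesh)

    def test_tiny_negative_clamped(self, single_cell_mesh):
        s = State(np.array([[-1e-13]]), np.zeros(1))
        assert np.isfinite(discrete_entropy(s, single_cell_mesh))


class TestEntropyProduction:
    def test_constant_state_produces_nothing(self):
        mesh = build_rectangular_mesh(4, 4)
        s = State(np.full((2, mesh.n_cells), 0.2), np.zeros(mesh.n_cells))
        assert entropy_production(s, mesh, drift_free_params(2)) == 0.0

    def test_two_cell_direct_evaluation(self, two_cell_mesh):
        # tau = 2, D = 1, u1 = (0.3, 0.1):
        # I = 2 [4*0.9 (sqrt .3 - sqrt .1)^2 + 4 (sqrt .7 - sqrt .9)^2 + 0.04]
        s = two_cell_state([[0.3, 0.1]])
        expected = 2.0 * (
            4.0 * 0.9 * (np.sqrt(0.3) - np.sqrt(0.1)) ** 2
            + 4.0 * (np.sqrt(0.7) - np.sqrt(0.9)) ** 2
            + 0.2**2
        )
        I = entropy_production(s, two_cell_mesh, drift_free_params())
        assert I == pytest.approx(expected)
        assert I == pytest.approx(0.5662405, abs=1e-6)

    def test_nonnegative_on_random_states(self):
        mesh = build_rectangular_mesh(5, 5)
        p = drift_free_params(3)
        for seed in range(50):
            s = random_admissible_state(mesh, 3, seed)
            assert entropy_production(s, mesh, p) >= 0.0

    def test_requires_drift_free_equal_d(self, two_cell_mesh):
        s = two_cell_state([[0.3, 0.1]])
        with pytest.raises(ValueError):
            entropy_production(s, two_cell_mesh,
                               ModelParams(n=1, D=[1.0], z=[1.0], drift_enabled=True))


class TestEntropyInequality:
    def test_equilibrium_trajectory_is_flat(self):
        mesh = build_rectangular_mesh(3, 3)
        s = State(np.full((1, mesh.n_cells), 0.4), np.zeros(mesh.n_cells))
        series = entropy_inequality_series([s, s, s], mesh, drift_free_params(), 1e-3)
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_dissipation_along_a_run(self):
        mesh = build_rectangular_mesh(8, 8)
        p = drift_free_params(2)
        state = random_admissible_state(mesh, 2, seed=2)
        cfg = SolverConfig(dt=1e-3, max_steps=30, steady_tol=1e-300)
        res = run_transient(state, mesh, p, BoundaryData.empty(2), cfg)
        series = entropy_inequality_series(res.trajectory, mesh, p, cfg.dt)
        assert series.max() <= 1e-8
        H = [r.entropy for r in res.records]
        assert all(H[i + 1] <= H[i] + 1e-12 for i in range(len(H) - 1))


class TestRelativeEntropy:
    def test_zero_at_the_steady_state(self):
        mesh = build_rectangular_mesh(3, 3)
        p = drift_free_params(2)
        s = random_admissible_state(mesh, 2, seed=0)
        assert relative_entropy(s, s, mesh, p) == pytest.approx(0.0, abs=1e-14)

    def test_constant_potential_shift_has_no_quadratic_term(self):
        # all-Neumann mesh: only internal edge differences enter, and a
        # constant shift of phi - phi_inf cancels
        mesh = build_rectangular_mesh(3, 3)
        p = drift_free_params(1)
        u = np.full((1, mesh.n_cells), 0.3)
        a = State(u, np.full(mesh.n_cells, 5.0))
        b = State(u.copy(), np.zeros(mesh.n_cells))
        assert relative_entropy(a, b, mesh, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_direct_evaluation(self, two_cell_mesh):
        p = ModelParams(n=1, D=[1.0], z=[1.0], lam2=0.5, drift_enabled=False)
        s = two_cell_state([[0.3, 0.2]], phi=(0.1, 0.0))
        ref = two_cell_state([[0.25, 0.25]], phi=(0.0, 0.0))
        m = 0.5
        boltz = m * (
            0.3 * np.log(0.3 / 0.25) + 0.7 * np.log(0.7 / 0.75)
            + 0.2 * np.log(0.2 / 0.25) + 0.8 * np.log(0.8 / 0.75)
        )
        quad = 0.5 * 0.5 * 2.0 * (0.1 - 0.0) ** 2  # lam2/2 * tau * (dphi)^2
        E = relative_entropy(s, ref, two_cell_mesh, p)
        assert E == pytest.approx(boltz + quad)
        assert E >= 0.0

    def test_incompatible_support_raises(self, two_cell_mesh):
        p = drift_free_params(1)
        s = two_cell_state([[0.3, 0.2]])
        ref = two_cell_state([[0.0, 0.25]])
        with pytest.raises(ValueError):
            relative_entropy(s, ref, two_cell_mesh, p)


class TestNormsAndGradients:
    def test_h1_norm_basics(self, two_cell_mesh):
        assert discrete_h1_norm(np.zeros(2), two_cell_mesh) == 0.0
        assert discrete_h1_norm(np.ones(2), two_cell_mesh) == pytest.approx(1.0)
        # tau = 2, v = (0, 1): sqrt(2 * 1 + 0.5 * 1) = sqrt(2.5)
        assert discrete_h1_norm(np.array([0.0, 1.0]), two_cell_mesh) == pytest.approx(
            np.sqrt(2.5)
        )

    def test_gradient_zero_for_constants(self, two_cell_mesh):
        g = discrete_gradient(np.full(2, 0.7), two_cell_mesh)
        np.testing.assert_allclose(g, 0.0)

    def test_gradient_two_cell_value(self, two_cell_mesh):
        # m(sigma) (v_L - v_K)/m(T_KL) n_KL = 1*0.3/0.25 * (1, 0)
        g = discrete_gradient(np.array([0.0, 0.3]), two_cell_mesh)
        e = int(two_cell_mesh.internal_edges[0])
        np.testing.assert_allclose(g[e], [1.2, 0.0], atol=1e-14)
        # exterior edges carry no diamond
        for b in two_cell_mesh.neumann_edges:
            np.testing.assert_allclose(g[b], 0.0)

    def test_gradient_integral_identity(self, two_cell_mesh):
        # integral over T_KL equals m(sigma)(v_L - v_K) n_KL by construction
        v = np.array([0.2, 0.9])
        e = int(two_cell_mesh.internal_edges[0])
        g = discrete_gradient(v, two_cell_mesh)
        lhs = g[e] * two_cell_mesh.edge_dual_measure[e]
        rhs = two_cell_mesh.edge_measure[e] * 0.7 * two_cell_mesh.edge_normal[e]
        np.testing.assert_allclose(lhs, rhs, atol=1e-14)


class TestErrorsAndOrders:
    def test_l1_error_trivial_cases(self):
        coarse = build_rectangular_mesh(2, 2)
        fine = refine_mesh(coarse)
        anc = ancestor_indices([coarse, fine])
        zero = np.zeros((1, coarse.n_cells))
        one = np.ones((1, fine.n_cells))
        assert l1_error(zero, np.zeros((1, fine.n_cells)), fine, anc)[0] == 0.0
        assert l1_error(zero, one, fine, anc)[0] == pytest.approx(1.0)
        # constant offset c -> c |Omega|
        assert l1_error(zero + 0.25, np.zeros((1, fine.n_cells)), fine, anc)[0] == pytest.approx(0.25)

    def test_l1_error_shape_mismatch(self):
        coarse = build_rectangular_mesh(2, 2)
        fine = refine_mesh(coarse)
        with pytest.raises(ValueError):
            l1_error(np.zeros((1, 4)), np.zeros((1, 5)), fine, np.zeros(3, dtype=int))

    def test_convergence_order_exact_ratios(self):
        h = np.array([0.1, 0.05])
        assert convergence_order(h, np.array([[1e-2], [5e-3]]))[0] == pytest.approx(1.0)
        assert convergence_order(h, np.array([[1e-2], [2.5e-3]]))[0] == pytest.approx(2.0)

    def test_convergence_order_rejects_bad_input(self):
        with pytest.raises(ValueError):
            convergence_order(np.array([0.1]), np.array([[1e-2]]))
        with pytest.raises(ValueError):
            convergence_order(np.array([0.1, 0.05]), np.array([[1e-2], [0.0]]))


class TestBoundsReport:
    def test_clean_trajectory_has_no_flags(self):
        mesh = build_rectangular_mesh(4, 4)
        states = [random_admissible_state(mesh, 2, seed=s) for s in range(3)]
        rep = bounds_and_mass_report(states, mesh, check_mass=False)
        assert not rep.negative_flag
        assert not rep.overfill_flag

    def test_overfilled_state_is_flagged(self):
        mesh = build_rectangular_mesh(2, 2)
        s = State(np.full((2, mesh.n_cells), 0.6), np.zeros(mesh.n_cells))
        rep = bounds_and_mass_report([s], mesh, check_mass=False)
        assert rep.overfill_flag

    def test_negative_state_is_flagged(self):
        mesh = build_rectangular_mesh(2, 2)
        s = State(np.full((1, mesh.n_cells), -1e-3), np.zeros(mesh.n_cells))
        rep = bounds_and_mass_report([s], mesh, check_mass=False)
        assert rep.negative_flag
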