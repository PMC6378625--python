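import numpy as np
import pytest

from ionfv import (
    BoundaryData,
    ModelParams,
    State,
    assemble_poisson,
    assemble_residual,
    build_rectangular_mesh,
    edge_difference,
    edge_upwind_states,
    flux_general,
    flux_reformulated,
    flux_simplified,
    flux_truncated,
)
from ionfv.scheme import _upwind_core, _flux_from_upwind
from ionfv.studies import flux_all_variants, random_edge_sides

from conftest import drift_free_params, two_cell_state


def drift_params(n=1, z=1.0, truncated=False):
    z = np.full(n, z) if np.isscalar(z) else np.asarray(z)
    return ModelParams(n=n, D=np.ones(n), z=z, beta=1.0,
                       drift_enabled=True, truncation_enabled=truncated)


class TestEdgeDifference:
    def test_internal(self, two_cell_mesh):
        e = int(two_cell_mesh.internal_edges[0])
        assert edge_difference(two_cell_mesh, e, np.array([0.2, 0.5])) == pytest.approx(0.3)

    def test_dirichlet_uses_trace(self, two_cell_mesh):
        two_cell_mesh.set_boundary_tags(lambda m: m[:, 0] < 1e-12)
        e = int(two_cell_mesh.dirichlet_edges[0])
        v = np.array([0.4, 0.0])
        assert edge_difference(two_cell_mesh, e, v, trace=0.1) == pytest.approx(-0.3)
        with pytest.raises(ValueError):
            edge_difference(two_cell_mesh, e, v)

    def test_neumann_is_zero(self, two_cell_mesh):
        e = int(two_cell_mesh.neumann_edges[0])
        assert edge_difference(two_cell_mesh, e, np.array([3.0, 7.0])) == 0.0


class TestUpwindStates:
    def test_solvent_mobility_is_the_max(self, two_cell_mesh):
        # u0K = 0.3, u0L = 0.7
        state = two_cell_state([[0.7, 0.3]])
        e = int(two_cell_mesh.internal_edges[0])
        u0s, _, _, _ = edge_upwind_states(
            state, two_cell_mesh, drift_free_params(), BoundaryData.empty(1), e, 0
        )
        assert u0s == pytest.approx(0.7)

    def test_drift_free_rule_reduces_to_solvent_sign(self, two_cell_mesh):
        # u0K = 0.2 < u0L = 0.6  ->  upwind value is the K side
        state = two_cell_state([[0.8, 0.4]])
        e = int(two_cell_mesh.internal_edges[0])
        _, _, V, u_upw = edge_upwind_states(
            state, two_cell_mesh, drift_free_params(), BoundaryData.empty(1), e, 0
        )
        assert V == pytest.approx(0.4)
        assert u_upw == pytest.approx(0.8)

    def test_double_upwind_hand_case(self, two_cell_mesh):
        # beta = z = 1, Phi = (0, -1), u1 = (0.2, 0.4):
        # D(Phi) = -1 < 0 -> uhat = u0L = 0.6; V = -0.2 + 0.6 = 0.4 -> u = u1K
        state = two_cell_state([[0.2, 0.4]], phi=(0.0, -1.0))
        e = int(two_cell_mesh.internal_edges[0])
        u0s, uhat, V, u_upw = edge_upwind_states(
            state, two_cell_mesh, drift_params(), BoundaryData.empty(1), e, 0
        )
        assert u0s == pytest.approx(0.8)
        assert uhat == pytest.approx(0.6)
        assert V == pytest.approx(0.4)
        assert u_upw == pytest.approx(0.2)


class TestFluxVariants:
    def test_general_hand_value(self, two_cell_mesh):
        # tau = 2 on this mesh; the hand case above with tau = 1 gives -0.08,
        # so here the flux is -0.16
        state = two_cell_state([[0.2, 0.4]], phi=(0.0, -1.0))
        e = int(two_cell_mesh.internal_edges[0])
        F = flux_general(state, two_cell_mesh, drift_params(), None, e, 0)
        assert F == pytest.approx(2 * -0.08)

    def test_constant_state_zero_flux(self, two_cell_mesh):
        state = two_cell_state([[0.3, 0.3]])
        e = int(two_cell_mesh.internal_edges[0])
        assert flux_general(state, two_cell_mesh, drift_params(), None, e, 0) == 0.0

    def test_neumann_flux_vanishes(self, two_cell_mesh):
        state = two_cell_state([[0.2, 0.7]])
        e = int(two_cell_mesh.neumann_edges[0])
        assert flux_general(state, two_cell_mesh, drift_params(), None, e, 0) == 0.0

    def test_truncation_inactive_on_admissible_states(self, two_cell_mesh):
        state = two_cell_state([[0.25, 0.55]], phi=(0.3, -0.4))
        e = int(two_cell_mesh.internal_edges[0])
        p = drift_params()
        assert flux_truncated(state, two_cell_mesh, p, None, e, 0) == pytest.approx(
            flux_general(state, two_cell_mesh, p, None, e, 0)
        )

    def test_truncation_clamps_negative_upwind_value(self):
        # u1K = -0.1 chosen by the upwind rule is treated as 0
        p = ModelParams(n=1, D=[1.0], z=[0.0], drift_enabled=False,
                        truncation_enabled=True)
        # both sides negative so the upwind rule selects a negative value:
        # du0 = u0O - u0K = 1.1 - 1.2 < 0 -> V < 0 -> the O side (-0.1)
        uK = np.array([[-0.2]])   # u0K = 1.2
        uO = np.array([[-0.1]])   # u0O = 1.1
        us = np.zeros(1)
        up = _upwind_core(uK, uO, us, us, np.zeros(1), np.zeros(1), p,
                          drift=False, truncated=True)
        assert not up.selupwK[0, 0]
        assert up.u_upwind[0, 0] == 0.0  # the chosen value (-0.1)+ = 0

    def test_truncation_clamps_overfilled_solvent(self):
        p = ModelParams(n=2, D=[1.0, 1.0], z=[0.0, 0.0], drift_enabled=False,
                        truncation_enabled=True)
        uK = np.array([[0.7], [0.5]])  # sum = 1.2 -> u0K = 0
        uO = np.array([[0.1], [0.1]])
        us = np.zeros(1)
        up = _upwind_core(uK, uO, us, us, np.zeros(1), np.zeros(1), p,
                          drift=False, truncated=True)
        assert up.u0K[0] == 0.0

    def test_simplified_hand_value(self, two_cell_mesh):
        # tau=2, D=1, u1=(0.3, 0.1): F = -2[0.9(-0.2) - 0.3(0.2)] = 0.48
        state = two_cell_state([[0.3, 0.1]])
        e = int(two_cell_mesh.internal_edges[0])
        p = drift_free_params()
        assert flux_simplified(state, two_cell_mesh, p, e, 0) == pytest.approx(0.48)
        assert flux_reformulated(state, two_cell_mesh, p, e, 0) == pytest.approx(0.48)

    def test_simplified_requires_drift_off(self, two_cell_mesh):
        state = two_cell_state([[0.3, 0.1]])
        e = int(two_cell_mesh.internal_edges[0])
        with pytest.raises(ValueError):
            flux_simplified(state, two_cell_mesh, drift_params(), e, 0)
        with pytest.raises(ValueError):
            flux_reformulated(state, two_cell_mesh, drift_params(), e, 0)

    def test_equal_fields_give_zero_flux(self, two_cell_mesh):
        state = two_cell_state([[0.42, 0.42]])
        e = int(two_cell_mesh.internal_edges[0])
        assert flux_simplified(state, two_cell_mesh, drift_free_params(), e, 0) == 0.0


class TestFluxIdentities:
    """Randomized identities among the flux variants."""

    def test_reformulated_equals_simplified(self):
        rng = np.random.default_rng(42)
        p = ModelParams(n=3, D=np.ones(3), z=np.zeros(3),
                        drift_enabled=False, truncation_enabled=False)
        uK, uO, phiK, phiO, tau = random_edge_sides(rng, 3, 10000)
        F = flux_all_variants(uK, uO, phiK, phiO, tau, p)
        assert np.abs(F["reformulated"] - F["simplified"]).max() < 1e-12

    def test_simplified_equals_general_without_potential(self):
        rng = np.random.default_rng(43)
        p = ModelParams(n=2, D=np.ones(2), z=np.zeros(2),
                        drift_enabled=False, truncation_enabled=False)
        uK, uO, phiK, phiO, tau = random_edge_sides(rng, 2, 10000)
        F = flux_all_variants(uK, uO, phiK, phiO, tau, p)
        assert np.abs(F["simplified"] - F["general"]).max() < 1e-12

    def test_single_species_closed_form(self):
        # n=1, drift off: F = -tau D (1 + |u_K - u_L|)(u_L - u_K)
        rng = np.random.default_rng(44)
        p = ModelParams(n=1, D=[1.0], z=[0.0], drift_enabled=False,
                        truncation_enabled=False)
        uK, uO, phiK, phiO, tau = random_edge_sides(rng, 1, 10000)
        F = flux_all_variants(uK, uO, phiK, phiO, tau, p)["simplified"]
        du = uO[0] - uK[0]
        expected = -tau * (1.0 + np.abs(du)) * du
        np.testing.assert_allclose(F[0], expected, atol=1e-13)

    def test_edge_sum_identity(self):
        # sum_{i=0}^n u_i_sigma = 1 + |u0K - u0L| under the drift-free rule
        rng = np.random.default_rng(45)
        n = 3
        p = ModelParams(n=n, D=np.ones(n), z=np.zeros(n),
                        drift_enabled=False, truncation_enabled=False)
        uK, uO, *_ = random_edge_sides(rng, n, 10000)
        us = np.zeros(uK.shape[1])
        up = _upwind_core(uK, uO, us, us, us, us, p, drift=False, truncated=False)
        u0_upw = np.where(up.du0 <= 0, up.u0K, up.u0O)
        lhs = u0_upw + up.u_upwind.sum(axis=0)
        rhs = 1.0 + np.abs(up.u0K - up.u0O)
        np.testing.assert_allclose(lhs, rhs, atol=1e-13)

    def test_dirichlet_edge_flux_uses_trace(self, two_cell_mesh):
        two_cell_mesh.set_boundary_tags(lambda m: m[:, 0] < 1e-12)
        state = two_cell_state([[0.3, 0.3]])
        bd = BoundaryData(np.array([[0.1]]), np.array([0.0]))
        e = int(two_cell_mesh.dirichlet_edges[0])
        p = drift_free_params()
        # u0K = 0.7, trace u0 = 0.9, du = -0.2, du0 = +0.2, upwind = K side;
        # the boundary edge has m = 1, d = 0.25, so tau = 4:
        # F = -4 [0.9*(-0.2) - 0.3*(0.2)] = 0.96
        F = flux_general(state, two_cell_mesh, p, bd, e, 0)
        assert F == pytest.approx(0.96)


class TestPoisson:
    def test_exact_for_linear_potential(self):
        mesh = build_rectangular_mesh(6, 5)
        mesh.set_boundary_tags(lambda m: np.ones(len(m), dtype=bool))
        p = ModelParams(n=1, D=[1.0], z=[0.0], lam2=2.5, drift_enabled=True)
        mids = mesh.edge_midpoints[mesh.dirichlet_edges]
        bd = BoundaryData(np.zeros((1, len(mids))), 3.0 * mids[:, 0] - 1.0)
        phi = assemble_poisson(np.zeros((1, mesh.n_cells)), mesh, p, bd)
        np.testing.assert_allclose(phi, 3.0 * mesh.cell_centers[:, 0] - 1.0,
                                   atol=1e-12)

    def test_constant_trace_zero_charge(self):
        mesh = build_rectangular_mesh(4, 4)
        mesh.set_boundary_tags(lambda m: m[:, 0] < 1e-12)
        p = ModelParams(n=1, D=[1.0], z=[1.0], lam2=1.0, drift_enabled=True)
        bd = BoundaryData.constant(mesh, np.array([0.0]), phi_value=2.5)
        phi = assemble_poisson(np.zeros((1, mesh.n_cells)), mesh, p, bd)
        np.testing.assert_allclose(phi, 2.5, atol=1e-12)

    def test_pure_neumann_raises(self):
        mesh = build_rectangular_mesh(3, 3)
        p = ModelParams(n=1, D=[1.0], z=[1.0], drift_enabled=True)
        with pytest.raises(ValueError, match="drift"):
            assemble_poisson(np.zeros((1, mesh.n_cells)), mesh, p,
                             BoundaryData.empty(1))


class TestResidual:
    def test_single_cell_reduces_to_time_derivative(self, single_cell_mesh):
        p = drift_free_params()
        old = State(np.array([[0.3]]), np.zeros(1))
        new = State(np.array([[0.42]]), np.zeros(1))
        dt = 0.1
        R = assemble_residual(new, old, single_cell_mesh, p, None, dt)
        assert R[0] == pytest.approx(1.0 * (0.42 - 0.3) / dt)

    def test_constant_state_is_equilibrium(self):
        mesh = build_rectangular_mesh(4, 3)
        p = drift_free_params(n=2)
        u = np.tile(np.array([[0.2], [0.3]]), (1, mesh.n_cells))
        s = State(u, np.zeros(mesh.n_cells))
        R = assemble_residual(s, s, mesh, p, None, 1e-3)
        np.testing.assert_allclose(R, 0.0, atol=1e-15)

    def test_flux_sum_telescopes_on_all_neumann_mesh(self):
        # sum_K residual_(i,K) = sum_K m(K)(u^k - u^{k-1})/dt exactly
        mesh = build_rectangular_mesh(5, 4)
        p = drift_free_params(n=2)
        rng = np.random.default_rng(7)
        old = State(rng.uniform(0.05, 0.4, (2, mesh.n_cells)), np.zeros(mesh.n_cells))
        new = State(rng.uniform(0.05, 0.4, (2, mesh.n_cells)), np.zeros(mesh.n_cells))
        dt = 1e-2
        R = assemble_residual(new, old, mesh, p, None, dt).reshape(2, -1)
        expect = (mesh.cell_measures[None, :] * (new.u - old.u) / dt).sum(axis=1)
        np.testing.assert_allclose(R.sum(axis=1), expect, atol=1e-12)

    def test_invalid_dt_rejected(self, single_cell_mesh):
        p = drift_free_params()
        s = State(np.array([[0.3]]), np.zeros(1))
        with pytest.raises(ValueError):
            assemble_residual(s, s, single_cell_mesh, p, None, 0.0)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestFluxHypothesis:
    @settings(deadline=None, max_examples=100)
    @given(
        uK=st.floats(0.0, 0.95), uL=st.floats(0.0, 0.95),
        tau=st.floats(0.1, 10.0),
    )
    def test_single_species_flux_closed_form_pointwise(self, uK, uL, tau):
        # n = 1, drift off: F = -tau D (1 + |du|) du with du = u_L - u_K
        p = ModelParams(n=1, D=[1.0], z=[0.0], drift_enabled=False,
                        truncation_enabled=False)
        F = flux_all_variants(np.array([[uK]]), np.array([[uL]]),
                              np.zeros(1), np.zeros(1), np.array([tau]), p)
        du = uL - uK
        expected = -tau * (1.0 + abs(du)) * du
        assert F["simplified"][0, 0] == pytest.approx(expected, abs=1e-12)
        # conservativity under side swap is exact
        FL = flux_all_variants(np.array([[uL]]), np.array([[uK]]),
                               np.zeros(1), np.zeros(1), np.array([tau]), p)
        assert F["simplified"][0, 0] + FL["simplified"][0, 0] == 0.0
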