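"""Structure functionals of the scheme: entropy, entropy production,
relative entropy, discrete norms, gradients, errors and conservation checks.

The central Lyapunov functional is the discrete Boltzmann entropy

    H = sum_K m(K) sum_{i=0}^n h(u_{i,K}),   h(z) = z log z - z + 1,

with h(0) = 1 by continuous extension.  For the drift-free equal-diffusivity
scheme every implicit Euler step dissipates H at the rate of the nonnegative
entropy production

    I = D sum_{internal sigma} tau_sigma [ 4 sum_i u0_sigma (sqrt u_iK -
        sqrt u_iL)^2 + 4 (sqrt u0K - sqrt u0L)^2 + (u0K - u0L)^2 ],

i.e. (H^k - H^{k-1})/dt + I^k <= 0 for every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh
from .scheme import BoundaryData, ModelParams, State

__all__ = [
    "DiagnosticsRecord",
    "ConvergenceStudyResult",
    "discrete_entropy",
    "entropy_production",
    "entropy_inequality_series",
    "relative_entropy",
    "discrete_h1_norm",
    "discrete_gradient",
    "l1_error",
    "convergence_order",
    "bounds_and_mass_report",
    "make_record",
]

_NEG_TOL = 1e-12


@dataclass
class DiagnosticsRecord:
    k: int
    entropy: float
    entropy_production: float | None
    masses: np.ndarray
    u_min: np.ndarray
    u_max: np.ndarray
    sum_max: float
    newton_iterations: int
    relative_entropy: float | None = None


@dataclass
class ConvergenceStudyResult:
    h: np.ndarray                 # mesh sizes, decreasing
    errors: np.ndarray            # (levels, n) L1 errors per species
    orders: np.ndarray            # fitted order per species

    @property
    def order(self) -> float:
        return float(self.orders.mean())


def _clamped(u: np.ndarray) -> np.ndarray:
    if np.any(u < -_NEG_TOL):
        raise ValueError(
            f"concentration below -{_NEG_TOL:g} (min {u.min():.3e}); "
            "state is not admissible"
        )
    return np.maximum(u, 0.0)


def _h(z: np.ndarray) -> np.ndarray:
    # z log z - z + 1 with the continuous extension h(0) = 1
    out = np.ones_like(z)
    pos = z > 0
    zp = z[pos]
    out[pos] = zp * np.log(zp) - zp + 1.0
    return out


def discrete_entropy(state: State, mesh: Mesh,
                     params: ModelParams | None = None) -> float:
    """H = sum_K m(K) sum_{i=0..n} [u (log u - 1) + 1] >= 0."""
    u = _clamped(state.u)
    u0 = _clamped(state.u0(params))
    per_cell = _h(u0) + _h(u).sum(axis=0)
    return float((mesh.cell_measures * per_cell).sum())


def entropy_production(state: State, mesh: Mesh, params: ModelParams) -> float:
    """Nonnegative dissipation rate of the drift-free equal-D scheme."""
    if params.drift_enabled:
        raise ValueError("entropy production is defined for the drift-free scheme")
    if not params.equal_D:
        raise ValueError("entropy production requires equal diffusivities")
    D = float(params.D[0])
    ii = mesh.internal_edges
    K = mesh.edge_cells[ii, 0]
    L = mesh.edge_cells[ii, 1]
    tau = mesh.edge_tau[ii]
    u = _clamped(state.u)
    u0 = _clamped(state.u0(params))
    su = np.sqrt(u)
    s0 = np.sqrt(u0)
    u0s = np.maximum(u0[K], u0[L])
    species = (u0s[None, :] * (su[:, K] - su[:, L]) ** 2).sum(axis=0)
    val = tau * (4.0 * species + 4.0 * (s0[K] - s0[L]) ** 2 + (u0[K] - u0[L]) ** 2)
    return float(D * val.sum())


def entropy_inequality_series(trajectory, mesh: Mesh, params: ModelParams,
                              dt: float) -> np.ndarray:
    """(H^k - H^{k-1})/dt + I^k for k = 1..N; every entry should be <= 0
    up to the nonlinear solver tolerance."""
    H = [discrete_entropy(s, mesh, params) for s in trajectory]
    out = np.empty(len(trajectory) - 1)
    for k in range(1, len(trajectory)):
        I = entropy_production(trajectory[k], mesh, params)
        out[k - 1] = (H[k] - H[k - 1]) / dt + I
    return out


def relative_entropy(state: State, steady_state: State, mesh: Mesh,
                     params: ModelParams,
                     boundary: BoundaryData | None = None) -> float:
    """Distance to the steady state: Boltzmann relative entropy plus the
    weighted squared potential difference

        E = sum_K m(K) sum_{i=0..n} u_i log(u_i/u_i^inf)
            + (lam2/2) sum_sigma tau_sigma (D_{K,sigma}(Phi - Phi^inf))^2,

    with 0 log(0/a) = 0; an incompatible support (u > 0 where u^inf = 0)
    raises."""
    u = np.vstack([_clamped(state.u0(params))[None, :], _clamped(state.u)])
    uinf = np.vstack([_clamped(steady_state.u0(params))[None, :],
                      _clamped(steady_state.u)])
    bad = (u > 0) & (uinf == 0)
    if np.any(bad):
        raise ValueError("incompatible supports: u > 0 where steady u = 0")
    ratio = np.ones_like(u)
    pos = u > 0
    ratio[pos] = u[pos] / uinf[pos]
    boltz = float((mesh.cell_measures[None, :] * u * np.log(ratio)).sum())

    dpsi = state.phi - steady_state.phi
    ii = mesh.internal_edges
    K = mesh.edge_cells[ii, 0]
    L = mesh.edge_cells[ii, 1]
    quad = (mesh.edge_tau[ii] * (dpsi[L] - dpsi[K]) ** 2).sum()
    dd = mesh.dirichlet_edges
    if len(dd):
        Kd = mesh.edge_cells[dd, 0]
        # both states carry the same Dirichlet trace, so D(Phi - Phi^inf)
        # reduces to -(Phi_K - Phi^inf_K)
        quad += (mesh.edge_tau[dd] * dpsi[Kd] ** 2).sum()
    return boltz + 0.5 * params.lam2 * float(quad)


def discrete_h1_norm(values: np.ndarray, mesh: Mesh) -> float:
    """(sum_internal tau (v_K - v_L)^2 + sum_K m(K) v_K^2)^(1/2)."""
    v = np.asarray(values, dtype=float)
    ii = mesh.internal_edges
    K = mesh.edge_cells[ii, 0]
    L = mesh.edge_cells[ii, 1]
    grad = (mesh.edge_tau[ii] * (v[K] - v[L]) ** 2).sum()
    mass = (mesh.cell_measures * v**2).sum()
    return float(np.sqrt(grad + mass))


def discrete_gradient(values: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Per-edge diamond-cell gradient, (n_edges, 2).

    On the diamond T_KL of an internal edge:  m(sigma) (v_L - v_K) / m(T_KL)
    times the unit normal n_KL; zero on exterior edges (no diamond)."""
    v = np.asarray(values, dtype=float)
    out = np.zeros((mesh.n_edges, 2))
    ii = mesh.internal_edges
    K = mesh.edge_cells[ii, 0]
    L = mesh.edge_cells[ii, 1]
    coef = mesh.edge_measure[ii] * (v[L] - v[K]) / mesh.edge_dual_measure[ii]
    out[ii] = coef[:, None] * mesh.edge_normal[ii]
    return out


def l1_error(u_coarse: np.ndarray, u_fine: np.ndarray, fine_mesh: Mesh,
             ancestors: np.ndarray) -> np.ndarray:
    """Per-species discrete L1 distance between a coarse field prolongated
    through the nested-refinement parent map and a fine field."""
    u_coarse = np.atleast_2d(u_coarse)
    u_fine = np.atleast_2d(u_fine)
    if u_fine.shape[1] != fine_mesh.n_cells or len(ancestors) != fine_mesh.n_cells:
        raise ValueError("field/mesh/ancestor shapes do not match")
    diff = np.abs(u_coarse[:, ancestors] - u_fine)
    return (fine_mesh.cell_measures[None, :] * diff).sum(axis=1)


def convergence_order(h: np.ndarray, errors: np.ndarray) -> np.ndarray:
    """Least-squares slope of log(error) against log(h), per species."""
    h = np.asarray(h, dtype=float)
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    if errors.shape[0] != len(h):
        errors = errors.T
    if len(h) < 2:
        raise ValueError("need at least two refinement levels")
    if np.any(errors <= 0):
        raise ValueError("errors must be positive to fit an order")
    return np.array([
        np.polyfit(np.log(h), np.log(errors[:, j]), 1)[0]
        for j in range(errors.shape[1])
    ])


@dataclass
class BoundsReport:
    u_min: np.ndarray          # (steps, n)
    u_max: np.ndarray
    sum_max: np.ndarray        # (steps,)
    masses: np.ndarray         # (steps, n)
    negative_flag: bool
    overfill_flag: bool
    mass_drift_flag: bool
    max_mass_drift: float


def bounds_and_mass_report(trajectory, mesh: Mesh, tol: float = 1e-10,
                           mass_tol: float | None = None,
                           check_mass: bool | None = None) -> BoundsReport:
    """Min/max/mass bookkeeping along a trajectory with violation flags.

    Mass conservation is only meaningful on all-Neumann meshes; by default it
    is checked when the mesh has no Dirichlet edges."""
    if check_mass is None:
        check_mass = len(mesh.dirichlet_edges) == 0
    if mass_tol is None:
        mass_tol = tol
    m = mesh.cell_measures
    u_min, u_max, sum_max, masses = [], [], [], []
    for s in trajectory:
        u_min.append(s.u.min(axis=1))
        u_max.append(s.u.max(axis=1))
        sum_max.append(s.u.sum(axis=0).max())
        masses.append((m[None, :] * s.u).sum(axis=1))
    u_min = np.array(u_min)
    u_max = np.array(u_max)
    sum_max = np.array(sum_max)
    masses = np.array(masses)
    drift = np.abs(masses - masses[0]).max() if check_mass and len(masses) else 0.0
    return BoundsReport(
        u_min=u_min,
        u_max=u_max,
        sum_max=sum_max,
        masses=masses,
        negative_flag=bool((u_min < -tol).any()),
        overfill_flag=bool((sum_max > 1.0 + tol).any()),
        mass_drift_flag=bool(check_mass and drift > mass_tol),
        max_mass_drift=float(drift),
    )


def make_record(state: State, mesh: Mesh, params: ModelParams,
                newton_iterations: int = 0,
                steady_state: State | None = None,
                boundary: BoundaryData | None = None) -> DiagnosticsRecord:
    m = mesh.cell_measures
    can_produce = (not params.drift_enabled) and params.equal_D
    try:
        H = discrete_entropy(state, mesh, params)
        I = entropy_production(state, mesh, params) if can_produce else None
    except ValueError:
        H, I = np.nan, None
    E = None
    if steady_state is not None:
        E = relative_entropy(state, steady_state, mesh, params, boundary)
    return DiagnosticsRecord(
        k=state.k,
        entropy=H,
        entropy_production=I,
        masses=(m[None, :] * state.u).sum(axis=1),
        u_min=state.u.min(axis=1),
        u_max=state.u.max(axis=1),
        sum_max=float(state.u.sum(axis=0).max()),
        newton_iterations=newton_iterations,
    )
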