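"""Double-upwind two-point fluxes and the implicit Euler residual.

The model tracks n ion species with volume fractions u_1..u_n and the solvent
fraction u_0 = 1 - sum_i u_i (size exclusion / volume filling).  Across an
edge sigma between cells K and L the numerical flux for species i is

    F_{i,K,sigma} = -tau_sigma D_i [ u0s * D(u_i) - uw_i * V_i ],
    V_i  = D(u_0) - uh_i * beta * z_i * D(Phi),

where D(v) is the two-point difference (v_L - v_K internally, trace - v_K on
Dirichlet edges, 0 on Neumann edges) and three upwind choices are made:

* ``u0s``  the solvent mobility, the larger of the two side values,
* ``uh_i`` the solvent weight of the electric drift, taken from the K side
  when z_i * D(Phi) >= 0 and from the other side otherwise,
* ``uw_i`` the species value upwinded by the sign of the composite drift V_i.

With the drift switched off and equal diffusivities this reduces to the
simplified flux, for which an algebraically identical square-root
reformulation exists (used by the convergence theory); both are exposed and
cross-checked.  A truncated variant replaces every upwind slot by its positive
part, which is what makes the bound-preservation argument constructive.

Each edge flux is evaluated once and scattered with opposite signs to K and
L, so discrete conservativity F_{i,K,sigma} + F_{i,L,sigma} = 0 holds exactly
in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import DIRICHLET, INTERNAL, NEUMANN, Mesh

__all__ = [
    "ModelParams",
    "BoundaryData",
    "State",
    "edge_difference",
    "edge_upwind_states",
    "flux_general",
    "flux_truncated",
    "flux_simplified",
    "flux_reformulated",
    "edge_fluxes",
    "assemble_poisson",
    "assemble_residual",
    "assemble_system",
    "UpwindStates",
]


@dataclass
class ModelParams:
    """Physical parameters of the ion-transport system.

    ``u_static`` is an optional per-cell volume fraction of immobile species
    (e.g. confined oxygen in the channel case); it reduces the available
    solvent fraction, u_0 = 1 - sum_i u_i - u_static, but does not evolve.
    Its charge enters through the background charge ``f``.
    """

    n: int
    D: np.ndarray
    z: np.ndarray
    beta: float = 1.0
    lam2: float = 1.0
    f: np.ndarray | None = None
    drift_enabled: bool = True
    truncation_enabled: bool = True
    u_static: np.ndarray | None = None

    def __post_init__(self):
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if self.n < 1:
            raise ValueError("need at least one species")
        if len(self.D) != self.n or len(self.z) != self.n:
            raise ValueError("D and z must have length n")
        if np.any(self.D <= 0):
            raise ValueError("diffusivities must be positive")
        if self.beta <= 0 or self.lam2 <= 0:
            raise ValueError("beta and lambda^2 must be positive")

    @property
    def equal_D(self) -> bool:
        return bool(np.all(self.D == self.D[0]))

    def f_cellwise(self, mesh: Mesh) -> np.ndarray:
        if self.f is None:
            return np.zeros(mesh.n_cells)
        f = np.asarray(self.f, dtype=float)
        if f.shape != (mesh.n_cells,):
            raise ValueError("background charge f has wrong shape")
        return f

    def u_static_cellwise(self, mesh: Mesh) -> np.ndarray:
        if self.u_static is None:
            return np.zeros(mesh.n_cells)
        us = np.asarray(self.u_static, dtype=float)
        if us.shape != (mesh.n_cells,):
            raise ValueError("u_static has wrong shape")
        return us


@dataclass
class BoundaryData:
    """Dirichlet traces, aligned with ``mesh.dirichlet_edges`` order.

    ``u_bar``  shape (n, n_dirichlet);  ``phi_bar`` shape (n_dirichlet,).
    ``u_static_bar`` is the immobile fraction evaluated on those edges.
    The solvent trace is the derived quantity
    u0_bar = 1 - sum_i u_bar_i - u_static_bar and must be nonnegative.
    """

    u_bar: np.ndarray
    phi_bar: np.ndarray
    u_static_bar: np.ndarray | None = None

    def __post_init__(self):
        self.u_bar = np.atleast_2d(np.asarray(self.u_bar, dtype=float))
        self.phi_bar = np.atleast_1d(np.asarray(self.phi_bar, dtype=float))
        if self.u_static_bar is None:
            self.u_static_bar = np.zeros(self.u_bar.shape[1])
        if np.any(self.u_bar < 0):
            raise ValueError("Dirichlet traces must be nonnegative")
        if np.any(self.u0_bar < -1e-14):
            raise ValueError("Dirichlet traces must satisfy sum_i u_i <= 1")

    @property
    def u0_bar(self) -> np.ndarray:
        return 1.0 - self.u_bar.sum(axis=0) - self.u_static_bar

    @staticmethod
    def empty(n: int) -> "BoundaryData":
        return BoundaryData(np.zeros((n, 0)), np.zeros(0))

    @staticmethod
    def constant(mesh: Mesh, u_values, phi_value=0.0) -> "BoundaryData":
        nd = len(mesh.dirichlet_edges)
        u_values = np.asarray(u_values, dtype=float)
        return BoundaryData(
            np.repeat(u_values[:, None], nd, axis=1),
            np.full(nd, float(phi_value)),
        )


@dataclass
class State:
    """Per-cell concentrations u (n, n_cells), potential phi, time index k."""

    u: np.ndarray
    phi: np.ndarray
    k: int = 0

    def __post_init__(self):
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.phi = np.asarray(self.phi, dtype=float)

    @property
    def n(self) -> int:
        return self.u.shape[0]

    def u0(self, params: ModelParams | None = None) -> np.ndarray:
        u0 = 1.0 - self.u.sum(axis=0)
        if params is not None and params.u_static is not None:
            u0 = u0 - np.asarray(params.u_static, dtype=float)
        return u0

    def copy(self) -> "State":
        return State(self.u.copy(), self.phi.copy(), self.k)


# ---------------------------------------------------------------------------
# edge gather machinery
# ---------------------------------------------------------------------------

class _EdgeIndex(NamedTuple):
    """Flux-carrying edges (internal + Dirichlet) of a mesh."""

    edges: np.ndarray      # global edge ids
    K: np.ndarray          # owner cell
    L: np.ndarray          # neighbour cell, -1 on Dirichlet edges
    is_int: np.ndarray     # bool
    tau: np.ndarray
    dir_pos: np.ndarray    # position into BoundaryData arrays (-1 if internal)


def _edge_index(mesh: Mesh) -> _EdgeIndex:
    cached = getattr(mesh, "_edge_index_cache", None)
    if cached is not None and cached[0] is mesh.edge_kind:
        return cached[1]
    act = np.nonzero(mesh.edge_kind != NEUMANN)[0]
    K = mesh.edge_cells[act, 0]
    L = mesh.edge_cells[act, 1]
    is_int = L >= 0
    dir_edges = mesh.dirichlet_edges  # sorted by construction
    dir_pos = np.full(len(act), -1, dtype=np.int64)
    if len(dir_edges):
        bb = ~is_int
        dir_pos[bb] = np.searchsorted(dir_edges, act[bb])
    ei = _EdgeIndex(act, K, L, is_int, mesh.edge_tau[act], dir_pos)
    mesh._edge_index_cache = (mesh.edge_kind, ei)
    return ei


def _gather_sides(state: State, mesh: Mesh, params: ModelParams,
                  boundary: BoundaryData, ei: _EdgeIndex):
    """Per-active-edge side values: own (K) and other (L or trace)."""
    n = params.n
    uK = state.u[:, ei.K]
    us = params.u_static_cellwise(mesh)
    usK = us[ei.K]
    phiK = state.phi[ei.K]

    uO = np.empty_like(uK)
    usO = np.empty(len(ei.K))
    phiO = np.empty(len(ei.K))
    ii = ei.is_int
    uO[:, ii] = state.u[:, ei.L[ii]]
    usO[ii] = us[ei.L[ii]]
    phiO[ii] = state.phi[ei.L[ii]]
    bb = ~ii
    if np.any(bb):
        pos = ei.dir_pos[bb]
        if boundary is None or boundary.u_bar.shape[1] == 0:
            raise ValueError("Dirichlet edges present but no boundary data")
        uO[:, bb] = boundary.u_bar[:, pos]
        usO[bb] = boundary.u_static_bar[pos]
        phiO[bb] = boundary.phi_bar[pos]
    return uK, uO, usK, usO, phiK, phiO


class UpwindStates(NamedTuple):
    """All per-edge upwind quantities (arrays over flux-carrying edges)."""

    u0K: np.ndarray        # solvent fraction, K side (truncated if requested)
    u0O: np.ndarray        # solvent fraction, other side
    u0_sigma: np.ndarray   # solvent mobility max(u0K, u0O)
    u0_hat: np.ndarray     # (n, E) drift solvent weight
    V: np.ndarray          # (n, E) composite drift
    u_upwind: np.ndarray   # (n, E) upwinded species value
    du: np.ndarray         # (n, E) two-point species difference
    du0: np.ndarray        # two-point solvent difference
    dphi: np.ndarray       # two-point potential difference
    # switch bookkeeping (frozen by the semismooth Newton):
    sel0K: np.ndarray      # u0_sigma taken from K side
    selhatK: np.ndarray    # (n, E) u0_hat taken from K side
    selupwK: np.ndarray    # (n, E) u_upwind taken from K side
    g0K: np.ndarray        # d u0K / d(-sum u) activity (truncation)
    g0O: np.ndarray
    gupw: np.ndarray       # (n, E) positive-part activity of u_upwind


def _upwind_core(uK, uO, usK, usO, phiK, phiO, params: ModelParams,
                 drift: bool, truncated: bool) -> UpwindStates:
    beta, z = params.beta, params.z
    u0K_raw = 1.0 - uK.sum(axis=0) - usK
    u0O_raw = 1.0 - uO.sum(axis=0) - usO
    if truncated:
        g0K = (u0K_raw > 0).astype(float)
        g0O = (u0O_raw > 0).astype(float)
        u0K = np.maximum(u0K_raw, 0.0)
        u0O = np.maximum(u0O_raw, 0.0)
    else:
        g0K = np.ones_like(u0K_raw)
        g0O = np.ones_like(u0O_raw)
        u0K, u0O = u0K_raw, u0O_raw

    sel0K = u0K >= u0O
    u0s = np.where(sel0K, u0K, u0O)
    if truncated:
        u0s = np.maximum(u0s, 0.0)  # max(0, u0K, u0O); redundant after clamp

    dphi = (phiO - phiK) if drift else np.zeros_like(phiK)
    du0 = u0O - u0K
    du = uO - uK

    if drift:
        zdphi = z[:, None] * dphi[None, :]
        selhatK = zdphi >= 0
        u0_hat = np.where(selhatK, u0K[None, :], u0O[None, :])
        V = du0[None, :] - u0_hat * beta * zdphi
    else:
        selhatK = np.ones((params.n, uK.shape[1]), dtype=bool)
        u0_hat = np.broadcast_to(u0K[None, :], uK.shape).copy()
        V = np.broadcast_to(du0[None, :], uK.shape).copy()

    selupwK = V >= 0
    u_upw = np.where(selupwK, uK, uO)
    if truncated:
        gupw = (u_upw > 0).astype(float)
        u_upw = np.maximum(u_upw, 0.0)
    else:
        gupw = np.ones_like(u_upw)

    return UpwindStates(u0K, u0O, u0s, u0_hat, V, u_upw, du, du0, dphi,
                        sel0K, selhatK, selupwK, g0K, g0O, gupw)


def _flux_from_upwind(up: UpwindStates, tau, D) -> np.ndarray:
    return -tau[None, :] * D[:, None] * (
        up.u0_sigma[None, :] * up.du - up.u_upwind * up.V
    )


# ---------------------------------------------------------------------------
# public per-edge operations (spec surface; built on the vectorized core)
# ---------------------------------------------------------------------------

def edge_difference(mesh: Mesh, edge: int, values: np.ndarray,
                    trace: float | None = None) -> float:
    """Two-point difference D_{K,sigma} v for a single edge.

    Internal: v_L - v_K.  Dirichlet: trace - v_K (the trace is required).
    Neumann: 0 (mirror value convention).
    """
    kind = mesh.edge_kind[edge]
    K, L = mesh.edge_cells[edge]
    if kind == INTERNAL:
        return float(values[L] - values[K])
    if kind == DIRICHLET:
        if trace is None:
            raise ValueError("Dirichlet edge requires a trace value")
        return float(trace - values[K])
    return 0.0


def _single_edge_upwind(state, mesh, params, boundary, edge, truncated):
    ei = _edge_index(mesh)
    pos = np.nonzero(ei.edges == edge)[0]
    if len(pos) == 0:
        raise ValueError("edge carries no flux (Neumann)")
    sides = _gather_sides(state, mesh, params, boundary, ei)
    up = _upwind_core(*sides, params, params.drift_enabled, truncated)
    return up, int(pos[0])


def edge_upwind_states(state: State, mesh: Mesh, params: ModelParams,
                       boundary: BoundaryData, edge: int, species: int,
                       truncated: bool | None = None):
    """(u0_sigma, u0_hat_i, V_i, u_i_sigma) for one edge and one species."""
    if truncated is None:
        truncated = params.truncation_enabled
    up, p = _single_edge_upwind(state, mesh, params, boundary, edge, truncated)
    i = species
    return (float(up.u0_sigma[p]), float(up.u0_hat[i, p]),
            float(up.V[i, p]), float(up.u_upwind[i, p]))


def edge_fluxes(state: State, mesh: Mesh, params: ModelParams,
                boundary: BoundaryData | None = None,
                truncated: bool | None = None) -> np.ndarray:
    """Oriented fluxes F_{i,K,sigma} on every edge, (n, n_edges).

    Neumann columns are exactly zero; the L-side flux of an internal edge is
    the negation of the returned value (single evaluation + scatter).
    """
    if truncated is None:
        truncated = params.truncation_enabled
    ei = _edge_index(mesh)
    sides = _gather_sides(state, mesh, params, boundary, ei)
    up = _upwind_core(*sides, params, params.drift_enabled, truncated)
    F_act = _flux_from_upwind(up, ei.tau, params.D)
    F = np.zeros((params.n, mesh.n_edges))
    F[:, ei.edges] = F_act
    return F


def flux_general(state: State, mesh: Mesh, params: ModelParams,
                 boundary: BoundaryData | None, edge: int, species: int) -> float:
    """Untruncated double-upwind flux F_{i,K,sigma} for one edge."""
    if mesh.edge_kind[edge] == NEUMANN:
        return 0.0
    up, p = _single_edge_upwind(state, mesh, params, boundary, edge, False)
    tau = mesh.edge_tau[edge]
    return float(-tau * params.D[species] * (
        up.u0_sigma[p] * up.du[species, p] - up.u_upwind[species, p] * up.V[species, p]
    ))


def flux_truncated(state: State, mesh: Mesh, params: ModelParams,
                   boundary: BoundaryData | None, edge: int, species: int) -> float:
    """Flux with positive-part truncation in every upwind slot."""
    if mesh.edge_kind[edge] == NEUMANN:
        return 0.0
    up, p = _single_edge_upwind(state, mesh, params, boundary, edge, True)
    tau = mesh.edge_tau[edge]
    return float(-tau * params.D[species] * (
        up.u0_sigma[p] * up.du[species, p] - up.u_upwind[species, p] * up.V[species, p]
    ))


def _require_simplified(params: ModelParams):
    if params.drift_enabled:
        raise ValueError("simplified flux requires the drift to be disabled")
    if not params.equal_D:
        raise ValueError("simplified flux requires equal diffusivities")


def flux_simplified(state: State, mesh: Mesh, params: ModelParams,
                    edge: int, species: int,
                    boundary: BoundaryData | None = None) -> float:
    """Drift-free equal-diffusivity flux
    F = -tau D [u0_sigma (u_iL - u_iK) - u_i_sigma (u0L - u0K)]."""
    _require_simplified(params)
    return flux_general(state, mesh, params, boundary, edge, species)


def flux_reformulated(state: State, mesh: Mesh, params: ModelParams,
                      edge: int, species: int,
                      boundary: BoundaryData | None = None) -> float:
    """Square-root reformulation of the simplified flux,

    F = tau D [ s (a^2? ...) ]  with a = sqrt(u0K), b = sqrt(u0L),
        s = sqrt(u0_sigma):
    F = tau D [ s (a u_iK - b u_iL) - u_i_sigma (a - b)(s + a + b) ],

    algebraically identical to the simplified flux under the drift-free
    upwind rule (the difference a (a-b)(u_L - u_sigma) vanishes for the
    upwind choice)."""
    _require_simplified(params)
    if mesh.edge_kind[edge] == NEUMANN:
        return 0.0
    up, p = _single_edge_upwind(state, mesh, params, boundary, edge, False)
    a = np.sqrt(max(up.u0K[p], 0.0))
    b = np.sqrt(max(up.u0O[p], 0.0))
    s = np.sqrt(max(up.u0_sigma[p], 0.0))
    i = species
    # reconstruct side values from du and the upwind choice
    if up.selupwK[i, p]:
        u_iK = up.u_upwind[i, p]
        u_iL = u_iK + up.du[i, p]
    else:
        u_iL = up.u_upwind[i, p]
        u_iK = u_iL - up.du[i, p]
    tau = mesh.edge_tau[edge]
    D = params.D[species]
    return float(tau * D * (
        s * (a * u_iK - b * u_iL)
        - up.u_upwind[i, p] * (a - b) * (s + (a + b))
    ))


# ---------------------------------------------------------------------------
# Poisson equation
# ---------------------------------------------------------------------------

def assemble_poisson(u: np.ndarray, mesh: Mesh, params: ModelParams,
                     boundary: BoundaryData) -> np.ndarray:
    """Solve -lam2 * sum_sigma tau D(Phi) = m(K) (sum_i z_i u_i + f_K).

    Requires at least one Dirichlet edge for Phi (otherwise the operator is
    singular); with the drift disabled the potential is identically zero and
    this routine must not be called.
    """
    if len(mesh.dirichlet_edges) == 0:
        raise ValueError(
            "pure-Neumann Poisson problem is singular; disable the drift "
            "(Phi = 0) or tag Dirichlet edges"
        )
    lam2 = params.lam2
    Nc = mesh.n_cells
    ii = mesh.internal_edges
    K = mesh.edge_cells[ii, 0]
    L = mesh.edge_cells[ii, 1]
    tau = mesh.edge_tau[ii]
    dd = mesh.dirichlet_edges
    Kd = mesh.edge_cells[dd, 0]
    taud = mesh.edge_tau[dd]

    rows = np.concatenate([K, L, K, L, Kd])
    cols = np.concatenate([K, L, L, K, Kd])
    vals = lam2 * np.concatenate([tau, tau, -tau, -tau, taud])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(Nc, Nc)).tocsc()

    charge = (params.z[:, None] * u).sum(axis=0) + params.f_cellwise(mesh)
    rhs = mesh.cell_measures * charge
    np.add.at(rhs, Kd, lam2 * taud * boundary.phi_bar)
    return spla.spsolve(A, rhs)


# ---------------------------------------------------------------------------
# residual and Jacobian of one implicit Euler step
# ---------------------------------------------------------------------------

def pack_unknowns(state: State, drift: bool) -> np.ndarray:
    x = state.u.ravel()
    if drift:
        x = np.concatenate([x, state.phi])
    return x


def unpack_unknowns(x: np.ndarray, n: int, Nc: int, drift: bool,
                    phi_fixed: np.ndarray | None = None, k: int = 0) -> State:
    u = x[: n * Nc].reshape(n, Nc)
    phi = x[n * Nc:] if drift else (
        phi_fixed if phi_fixed is not None else np.zeros(Nc)
    )
    return State(u.copy(), np.asarray(phi, dtype=float).copy(), k)


def assemble_residual(new_state: State, old_state: State, mesh: Mesh,
                      params: ModelParams, boundary: BoundaryData | None,
                      dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    R, _ = _assemble(new_state, old_state, mesh, params, boundary, dt,
                     want_jacobian=False)
    return R


def assemble_system(new_state: State, old_state: State, mesh: Mesh,
                    params: ModelParams, boundary: BoundaryData | None,
                    dt: float):
    """Residual and exact (switch-frozen) sparse Jacobian."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return _assemble(new_state, old_state, mesh, params, boundary, dt,
                     want_jacobian=True)


def _assemble(new_state, old_state, mesh, params, boundary, dt, want_jacobian):
    n, Nc = params.n, mesh.n_cells
    if new_state.u.shape != (n, Nc):
        raise ValueError("state shape does not match mesh/params")
    drift = params.drift_enabled
    truncated = params.truncation_enabled

    ei = _edge_index(mesh)
    E = len(ei.edges)
    sides = _gather_sides(new_state, mesh, params, boundary, ei)
    up = _upwind_core(*sides, params, drift, truncated)
    F = _flux_from_upwind(up, ei.tau, params.D)  # (n, E)

    m = mesh.cell_measures
    R = (m[None, :] * (new_state.u - old_state.u) / dt)
    # scatter fluxes: +F to K, -F to L
    np.add.at(R, (slice(None), ei.K), F)
    ii = ei.is_int
    Rsub = np.zeros_like(R)
    np.add.at(Rsub, (slice(None), ei.L[ii]), F[:, ii])
    R -= Rsub
    Rvec = R.ravel()

    if drift:
        phi = new_state.phi
        dphi_full = np.zeros(E)
        dphi_full[ii] = phi[ei.L[ii]] - phi[ei.K[ii]]
        bb = ~ii
        if np.any(bb):
            dphi_full[bb] = boundary.phi_bar[ei.dir_pos[bb]] - phi[ei.K[bb]]
        G = np.zeros(Nc)
        np.add.at(G, ei.K, -params.lam2 * ei.tau * dphi_full)
        np.add.at(G, ei.L[ii], params.lam2 * ei.tau[ii] * dphi_full[ii])
        charge = (params.z[:, None] * new_state.u).sum(axis=0) + params.f_cellwise(mesh)
        G -= m * charge
        Rvec = np.concatenate([Rvec, G])

    if not want_jacobian:
        return Rvec, None

    # ---- Jacobian ---------------------------------------------------------
    z, beta, Dv = params.z, params.beta, params.D
    tauD = ei.tau[None, :] * Dv[:, None]  # (n, E)

    S0K = up.g0K * up.sel0K           # d u0_sigma / d(-u_jK) activity
    S0O = up.g0O * (~up.sel0K)
    zdphi = z[:, None] * up.dphi[None, :]
    # dP_i/du_jK = A_K[i] + delta_ij B_K[i];  P = u0s*du - uw*V;  F = -tauD*P
    A_K = (-up.du * S0K[None, :]
           - up.u_upwind * up.g0K[None, :] * (1.0 + up.selhatK * beta * zdphi))
    B_K = (-up.u0_sigma[None, :]
           - up.V * up.gupw * up.selupwK)
    A_L = (-up.du * S0O[None, :]
           + up.u_upwind * up.g0O[None, :] * (1.0 - (~up.selhatK) * beta * zdphi))
    B_L = (up.u0_sigma[None, :]
           - up.V * up.gupw * (~up.selupwK))
    # dP_i/dphiK = -uw_i * uh_i * beta z_i ; dP_i/dphiL = +uw_i * uh_i * beta z_i
    C_phi = up.u_upwind * up.u0_hat * beta * z[:, None]  # = dP/dphiL

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    iK = ei.K
    iL = ei.L
    idx_int = np.nonzero(ii)[0]

    # species-species blocks; row (i,K): column (j, side)
    ir = np.arange(n)
    # (i, j, E) column/row index helpers
    rowK = (ir[:, None, None] * Nc + iK[None, None, :])        # (n,1,E)
    colK = (ir[None, :, None] * Nc + iK[None, None, :])        # (1,n,E)
    JKK = -tauD[:, None, :] * (
        A_K[:, None, :] + np.eye(n)[:, :, None] * B_K[:, None, :]
    )  # (n, n, E): dF_i/du_jK
    add(np.broadcast_to(rowK, (n, n, E)), np.broadcast_to(colK, (n, n, E)), JKK)

    if len(idx_int):
        Li = iL[idx_int]
        rowKi = (ir[:, None, None] * Nc + iK[None, None, idx_int])
        rowLi = (ir[:, None, None] * Nc + Li[None, None, :])
        colKi = (ir[None, :, None] * Nc + iK[None, None, idx_int])
        colLi = (ir[None, :, None] * Nc + Li[None, None, :])
        JKL = -tauD[:, None, idx_int] * (
            A_L[:, None, idx_int] + np.eye(n)[:, :, None] * B_L[:, None, idx_int]
        )
        sh = (n, n, len(idx_int))
        add(np.broadcast_to(rowKi, sh), np.broadcast_to(colLi, sh), JKL)
        # row (i, L) = -row(i, K) derivatives
        JKKi = JKK[:, :, idx_int]
        add(np.broadcast_to(rowLi, sh), np.broadcast_to(colKi, sh), -JKKi)
        add(np.broadcast_to(rowLi, sh), np.broadcast_to(colLi, sh), -JKL)

    # time-derivative diagonal
    diag_rows = np.arange(n * Nc)
    add(diag_rows, diag_rows, np.repeat(m[None, :] / dt, n, axis=0))

    if drift:
        off = n * Nc
        # species rows, phi columns: dP_i/dphiK = -C_phi, dP_i/dphiL = +C_phi
        JphiK = tauD * C_phi       # dF_i/dphiK = -tauD * (-C_phi)
        JphiL = -tauD * C_phi      # dF_i/dphiL
        rphiK = ir[:, None] * Nc + iK[None, :]
        add(rphiK, off + np.broadcast_to(iK[None, :], (n, E)), JphiK)
        if len(idx_int):
            Li = iL[idx_int]
            add(ir[:, None] * Nc + iK[None, idx_int],
                off + np.broadcast_to(Li[None, :], (n, len(idx_int))),
                JphiL[:, idx_int])
            add(ir[:, None] * Nc + Li[None, :],
                off + np.broadcast_to(iK[None, idx_int], (n, len(idx_int))),
                -JphiK[:, idx_int])
            add(ir[:, None] * Nc + Li[None, :],
                off + np.broadcast_to(Li[None, :], (n, len(idx_int))),
                -JphiL[:, idx_int])

        # Poisson rows
        lam2 = params.lam2
        add(off + iK, off + iK, lam2 * ei.tau)
        if len(idx_int):
            Li = iL[idx_int]
            ti = ei.tau[idx_int]
            add(off + Li, off + Li, lam2 * ti)
            add(off + iK[idx_int], off + Li, -lam2 * ti)
            add(off + Li, off + iK[idx_int], -lam2 * ti)
        # charge coupling: dG_K/du_jK = -m_K z_j
        cells = np.arange(Nc)
        for j in range(n):
            add(off + cells, j * Nc + cells, -m * z[j])

    size = n * Nc + (Nc if drift else 0)
    J = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows).astype(np.int64),
          np.concatenate(cols).astype(np.int64))),
        shape=(size, size),
    ).tocsc()
    return Rvec, J
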