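"""Reusable experiment drivers: the nested-refinement L1 convergence study,
randomized structure checks (flux identities, conservativity, bounds,
entropy decay) and the bound-preservation runs.

These are the computations behind the ``convergence`` and ``check`` CLI
commands; tests and the acceptance script call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diagnostics as diag
from .cases import random_admissible_state
from .mesh import (
    Mesh,
    ancestor_indices,
    build_rectangular_mesh,
    refine_mesh,
)
from .scheme import (
    BoundaryData,
    ModelParams,
    State,
    _flux_from_upwind,
    _upwind_core,
    assemble_poisson,
)
from .solver import SolverConfig, run_transient

__all__ = [
    "smooth_initial_data",
    "l1_self_convergence",
    "random_edge_sides",
    "flux_all_variants",
    "max_conservativity_defect",
    "bound_preservation_runs",
    "entropy_inequality_run",
    "run_property_checks",
]


# ---------------------------------------------------------------------------
# convergence study
# ---------------------------------------------------------------------------

def _cos_cell_average(k: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Exact average of cos(k pi t) over [lo, hi]."""
    if k == 0:
        return np.ones_like(lo)
    kp = k * np.pi
    return (np.sin(kp * hi) - np.sin(kp * lo)) / (kp * (hi - lo))


def smooth_initial_data(mesh: Mesh, nx: int) -> np.ndarray:
    """Exact cell averages of two smooth admissible profiles on the unit
    square (uniform nx-by-nx rectangular mesh assumed):

        u_1 = 0.25 + 0.20 cos(pi x) cos(pi y)
        u_2 = 0.30 + 0.15 cos(2 pi x) cos(pi y)
    """
    h = 1.0 / nx
    xc, yc = mesh.cell_centers[:, 0], mesh.cell_centers[:, 1]
    xl, xr, yl, yr = xc - h / 2, xc + h / 2, yc - h / 2, yc + h / 2
    cx1 = _cos_cell_average(1.0, xl, xr)
    cx2 = _cos_cell_average(2.0, xl, xr)
    cy1 = _cos_cell_average(1.0, yl, yr)
    u1 = 0.25 + 0.20 * cx1 * cy1
    u2 = 0.30 + 0.15 * cx2 * cy1
    return np.vstack([u1, u2])


def l1_self_convergence(nx0: int = 16, levels: int = 3, dt: float = 1e-4,
                        steps: int = 500, seed: int = 0,
                        newton_tol: float = 1e-11) -> diag.ConvergenceStudyResult:
    """Drift-free two-species run on nested rectangular meshes; the solution
    on the finest (once more refined) mesh is the reference; errors are
    measured in the discrete L1 norm at the final time through the nested
    parent maps.  First-order convergence in h is expected."""
    params = ModelParams(n=2, D=[1.0, 1.0], z=[0.0, 0.0],
                         drift_enabled=False, truncation_enabled=False)
    meshes = [build_rectangular_mesh(nx0, nx0)]
    for _ in range(levels):
        meshes.append(refine_mesh(meshes[-1]))
    boundary = BoundaryData.empty(2)
    finals = []
    for lev, mesh in enumerate(meshes):
        nx = nx0 * 2**lev
        u0 = smooth_initial_data(mesh, nx)
        cfg = SolverConfig(dt=dt, max_steps=steps, newton_tol=newton_tol,
                           steady_tol=1e-300, store_trajectory=False,
                           record_every=max(1, steps))
        res = run_transient(State(u0, np.zeros(mesh.n_cells)), mesh, params,
                            boundary, cfg)
        finals.append(res.final)
    ref_mesh = meshes[-1]
    ref = finals[-1]
    hs, errs = [], []
    for lev in range(levels):
        anc = ancestor_indices(meshes[lev:])
        e = diag.l1_error(finals[lev].u, ref.u, ref_mesh, anc)
        hs.append(meshes[lev].h_max)
        errs.append(e)
    hs = np.array(hs)
    errs = np.array(errs)
    orders = diag.convergence_order(hs, errs)
    return diag.ConvergenceStudyResult(h=hs, errors=errs, orders=orders)


# ---------------------------------------------------------------------------
# randomized edge-state machinery
# ---------------------------------------------------------------------------

def random_edge_sides(rng: np.random.Generator, n: int, count: int,
                      admissible: bool = True):
    """Random two-sided edge states (uK, uO, phiK, phiO, tau).

    Admissible draws come from the scaled open simplex; inadmissible draws
    (for exercising the truncation) are uniform in [-0.2, 1.2]."""
    if admissible:
        uK = 0.95 * rng.dirichlet(np.ones(n + 1), size=count)[:, :n].T
        uO = 0.95 * rng.dirichlet(np.ones(n + 1), size=count)[:, :n].T
    else:
        uK = rng.uniform(-0.2, 1.2, size=(n, count))
        uO = rng.uniform(-0.2, 1.2, size=(n, count))
    phiK = rng.normal(size=count)
    phiO = rng.normal(size=count)
    tau = rng.uniform(0.5, 5.0, size=count)
    return uK, uO, phiK, phiO, tau


def flux_all_variants(uK, uO, phiK, phiO, tau, params: ModelParams):
    """Oriented K-side fluxes of every variant from raw side values.

    Returns a dict name -> (n, count) array.  The 'simplified' and
    'reformulated' entries are only present for drift-free equal-D
    parameters."""
    zeros = np.zeros_like(phiK)
    usz = np.zeros_like(phiK)
    out = {}
    up_gen = _upwind_core(uK, uO, usz, usz, phiK, phiO, params,
                          drift=params.drift_enabled, truncated=False)
    out["general"] = _flux_from_upwind(up_gen, tau, params.D)
    up_tr = _upwind_core(uK, uO, usz, usz, phiK, phiO, params,
                         drift=params.drift_enabled, truncated=True)
    out["truncated"] = _flux_from_upwind(up_tr, tau, params.D)
    if not params.drift_enabled and params.equal_D:
        up_s = _upwind_core(uK, uO, usz, usz, zeros, zeros, params,
                            drift=False, truncated=False)
        out["simplified"] = _flux_from_upwind(up_s, tau, params.D)
        a = np.sqrt(np.maximum(up_s.u0K, 0.0))
        b = np.sqrt(np.maximum(up_s.u0O, 0.0))
        s = np.sqrt(np.maximum(up_s.u0_sigma, 0.0))
        # the weight is summed as s + (a + b) so that swapping the two sides
        # negates the flux exactly in floating point
        out["reformulated"] = tau[None, :] * params.D[:, None] * (
            s[None, :] * (a[None, :] * uK - b[None, :] * uO)
            - up_s.u_upwind * (a - b)[None, :] * (s + (a + b))[None, :]
        )
    return out


def max_conservativity_defect(seed: int, n: int = 3, count: int = 10000) -> float:
    """max |F_{i,K,sigma} + F_{i,L,sigma}| over random edge states and all
    flux variants, with the L-side flux evaluated independently by swapping
    the two sides (the production code evaluates once and scatters, which is
    conservative by construction; the swap is the stronger check)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for admissible in (True, False):
        uK, uO, phiK, phiO, tau = random_edge_sides(rng, n, count // 2,
                                                    admissible=admissible)
        for drift in (True, False):
            params = ModelParams(n=n, D=np.ones(n), z=np.array([2.0, 1.0, -1.0])[:n],
                                 beta=1.0, lam2=1.0, drift_enabled=drift,
                                 truncation_enabled=False)
            FK = flux_all_variants(uK, uO, phiK, phiO, tau, params)
            FL = flux_all_variants(uO, uK, phiO, phiK, tau, params)
            for name in FK:
                worst = max(worst, float(np.abs(FK[name] + FL[name]).max()))
    return worst


# ---------------------------------------------------------------------------
# structure runs
# ---------------------------------------------------------------------------

def entropy_inequality_run(nx: int = 32, n: int = 3, steps: int = 200,
                           dt: float = 1e-3, seed: int = 0):
    """Drift-free equal-D run from random admissible data; returns the
    trajectory, the per-step entropy-inequality series and the mesh."""
    mesh = build_rectangular_mesh(nx, nx)
    params = ModelParams(n=n, D=np.ones(n), z=np.zeros(n),
                         drift_enabled=False, truncation_enabled=False)
    state = random_admissible_state(mesh, n, seed)
    cfg = SolverConfig(dt=dt, max_steps=steps, steady_tol=1e-300,
                       record_every=max(1, steps))
    res = run_transient(state, mesh, params, BoundaryData.empty(n), cfg)
    series = diag.entropy_inequality_series(res.trajectory, mesh, params, dt)
    return res.trajectory, series, mesh, params


def bound_preservation_runs(nx: int = 32, steps: int = 100, dt: float = 1e-3,
                            seed: int = 0):
    """The two bound-preservation experiments with equal diffusivities:

    (a) drift-free simplified scheme, all-Neumann, random admissible data;
    (b) truncated general scheme with drift (lam2 = 4.68e-4, beta = 1,
        charges +2/+1/-1), Dirichlet data on the two x-extremes, random
        admissible interior data.

    Returns (max over cells/steps of sum_i u_i, min over cells/steps of u_i).
    """
    n = 3
    sum_max = -np.inf
    u_min = np.inf

    # (a) simplified drift-free
    mesh = build_rectangular_mesh(nx, nx)
    params = ModelParams(n=n, D=np.ones(n), z=np.zeros(n),
                         drift_enabled=False, truncation_enabled=False)
    state = random_admissible_state(mesh, n, seed)
    cfg = SolverConfig(dt=dt, max_steps=steps, steady_tol=1e-300,
                       record_every=max(1, steps))
    res = run_transient(state, mesh, params, BoundaryData.empty(n), cfg)
    rep = diag.bounds_and_mass_report(res.trajectory, mesh)
    sum_max = max(sum_max, float(rep.sum_max.max()))
    u_min = min(u_min, float(rep.u_min.min()))

    # (b) truncated general scheme with drift
    mesh2 = build_rectangular_mesh(nx, nx)
    mesh2.set_boundary_tags(
        lambda mids: (mids[:, 0] < 1e-12) | (mids[:, 0] > 1 - 1e-12)
    )
    params2 = ModelParams(n=n, D=np.ones(n), z=np.array([2.0, 1.0, -1.0]),
                          beta=1.0, lam2=4.68e-4,
                          drift_enabled=True, truncation_enabled=True)
    boundary2 = BoundaryData.constant(mesh2, np.array([0.1, 0.1, 0.1]), 0.0)
    state2 = random_admissible_state(mesh2, n, seed + 1)
    state2.phi = assemble_poisson(state2.u, mesh2, params2, boundary2)
    cfg2 = SolverConfig(dt=dt, max_steps=steps, steady_tol=1e-300,
                        damping=True, newton_max_iter=50,
                        record_every=max(1, steps))
    res2 = run_transient(state2, mesh2, params2, boundary2, cfg2)
    rep2 = diag.bounds_and_mass_report(res2.trajectory, mesh2, check_mass=False)
    sum_max = max(sum_max, float(rep2.sum_max.max()))
    u_min = min(u_min, float(rep2.u_min.min()))
    return sum_max, u_min


# ---------------------------------------------------------------------------
# property-check suite (CLI `check`)
# ---------------------------------------------------------------------------

def run_property_checks(seed: int = 0):
    """Small, fast versions of the structure checks; returns a list of
    (name, passed, detail) tuples."""
    rng = np.random.default_rng(seed)
    results = []

    # flux equivalence: simplified == reformulated == general(phi == 0)
    n = 2
    params = ModelParams(n=n, D=np.ones(n), z=np.zeros(n),
                         drift_enabled=False, truncation_enabled=False)
    uK, uO, phiK, phiO, tau = random_edge_sides(rng, n, 2000)
    F = flux_all_variants(uK, uO, phiK, phiO, tau, params)
    dev = max(np.abs(F["simplified"] - F["reformulated"]).max(),
              np.abs(F["simplified"] - F["general"]).max())
    results.append(("flux equivalence", dev < 1e-12, f"max dev {dev:.2e}"))

    # edge identity: sum_{i=0}^n u_i_sigma = 1 + |u0K - u0L|
    usz = np.zeros_like(phiK)
    up = _upwind_core(uK, uO, usz, usz, np.zeros_like(phiK),
                      np.zeros_like(phiO), params, drift=False, truncated=False)
    u0_upw = np.where(up.du0 <= 0, up.u0K, up.u0O)  # same rule, species 0
    lhs = u0_upw + up.u_upwind.sum(axis=0)
    rhs = 1.0 + np.abs(up.u0K - up.u0O)
    dev = float(np.abs(lhs - rhs).max())
    results.append(("edge-sum identity", dev < 1e-12, f"max dev {dev:.2e}"))

    # conservativity
    worst = max_conservativity_defect(seed, count=2000)
    results.append(("flux conservativity", worst == 0.0, f"max defect {worst:.2e}"))

    # Poisson exactness for a linear potential on a uniform rectangular mesh
    mesh = build_rectangular_mesh(8, 8)
    mesh.set_boundary_tags(lambda mids: np.ones(len(mids), dtype=bool))
    p3 = ModelParams(n=1, D=[1.0], z=[0.0], lam2=1.0, drift_enabled=True)
    mids = mesh.edge_midpoints[mesh.dirichlet_edges]
    bd = BoundaryData(np.zeros((1, len(mids))), mids[:, 0])
    phi = assemble_poisson(np.zeros((1, mesh.n_cells)), mesh, p3, bd)
    dev = float(np.abs(phi - mesh.cell_centers[:, 0]).max())
    results.append(("Poisson exactness (linear)", dev < 1e-11, f"max dev {dev:.2e}"))

    # mass conservation + entropy inequality on a short run
    traj, series, mesh4, params4 = entropy_inequality_run(nx=8, n=2, steps=30,
                                                          dt=1e-3, seed=seed)
    rep = diag.bounds_and_mass_report(traj, mesh4)
    results.append(("mass conservation", rep.max_mass_drift < 1e-12,
                    f"max drift {rep.max_mass_drift:.2e}"))
    worst = float(series.max())
    results.append(("entropy inequality", worst <= 1e-8, f"max entry {worst:.2e}"))
    return results
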