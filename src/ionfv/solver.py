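"""Implicit Euler time stepping with a semismooth full Newton method.

The per-step nonlinear system couples all species (and, when the drift is
active, the potential) through the double-upwind fluxes.  The residual is
piecewise smooth; Newton freezes the upwind/positive-part switches at the
current iterate and uses the exact Jacobian of the resulting smooth branch,
re-evaluating the switches each iteration.  Linear systems are solved by a
sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import diagnostics as diag
from .mesh import Mesh
from .scheme import (
    BoundaryData,
    ModelParams,
    State,
    assemble_poisson,
    assemble_system,
    pack_unknowns,
    unpack_unknowns,
)

__all__ = [
    "SolverConfig",
    "TimeStepResult",
    "TransientResult",
    "NewtonFailure",
    "newton_solve",
    "advance_time_step",
    "run_transient",
    "solve_steady",
]


@dataclass
class SolverConfig:
    dt: float = 1e-3
    max_steps: int = 1000
    newton_tol: float = 1e-12        # inf-norm of the residual
    newton_max_iter: int = 30
    damping: bool = False            # halve the step on residual increase
    max_damping: int = 30
    steady_tol: float = 1e-12        # weighted L2 norm of consecutive states
    store_trajectory: bool = True
    record_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_tol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class TimeStepResult:
    state: State
    iterations: int
    residual_norm: float
    converged: bool
    residual_history: list = field(default_factory=list)


@dataclass
class TransientResult:
    trajectory: list          # list of State (or [initial, final] if not stored)
    records: list             # list of DiagnosticsRecord
    steps: int
    reached_steady: bool

    @property
    def final(self) -> State:
        return self.trajectory[-1]


class NewtonFailure(RuntimeError):
    def __init__(self, message, step=None, history=None):
        super().__init__(message)
        self.step = step
        self.history = history or []


def newton_solve(system, x0: np.ndarray, config: SolverConfig):
    """Root of ``system(x) -> (residual, jacobian)`` from the guess ``x0``.

    Returns (x, iterations, residual_norm, converged, history).  A singular
    Jacobian or exhausted damping is reported through converged=False, never
    silently.
    """
    x = x0.copy()
    R, J = system(x)
    rnorm = float(np.abs(R).max()) if len(R) else 0.0
    history = [rnorm]
    if rnorm <= config.newton_tol:
        return x, 0, rnorm, True, history
    for it in range(1, config.newton_max_iter + 1):
        try:
            # the Jacobian has symmetric structure (edge graph), for which
            # the AT+A minimum-degree ordering factorizes far faster
            dx = spla.splu(J.tocsc(), permc_spec="MMD_AT_PLUS_A").solve(-R)
        except RuntimeError:
            return x, it, rnorm, False, history
        if not np.all(np.isfinite(dx)):
            return x, it, rnorm, False, history
        step = 1.0
        x_new = x + dx
        R_new, J_new = system(x_new)
        rn = float(np.abs(R_new).max())
        if config.damping:
            halvings = 0
            while (not np.isfinite(rn) or rn > rnorm) and halvings < config.max_damping:
                step *= 0.5
                x_new = x + step * dx
                R_new, J_new = system(x_new)
                rn = float(np.abs(R_new).max())
                halvings += 1
            if not np.isfinite(rn) or (rn > rnorm and halvings >= config.max_damping):
                history.append(rn)
                return x, it, rnorm, False, history
        x, R, J, rnorm = x_new, R_new, J_new, rn
        history.append(rnorm)
        if rnorm <= config.newton_tol:
            return x, it, rnorm, True, history
    return x, config.newton_max_iter, rnorm, False, history


def advance_time_step(old_state: State, mesh: Mesh, params: ModelParams,
                      boundary: BoundaryData | None,
                      config: SolverConfig) -> TimeStepResult:
    """One implicit Euler step; the initial Newton guess is the old state."""
    drift = params.drift_enabled
    n, Nc = params.n, mesh.n_cells

    def system(x):
        st = unpack_unknowns(x, n, Nc, drift, phi_fixed=old_state.phi)
        return assemble_system(st, old_state, mesh, params, boundary, config.dt)

    x0 = pack_unknowns(old_state, drift)
    x, iters, rnorm, ok, hist = newton_solve(system, x0, config)
    new_state = unpack_unknowns(x, n, Nc, drift, phi_fixed=old_state.phi,
                                k=old_state.k + 1)
    return TimeStepResult(new_state, iters, rnorm, ok, hist)


def _state_difference_norm(a: State, b: State, mesh: Mesh) -> float:
    d2 = (mesh.cell_measures[None, :] * (a.u - b.u) ** 2).sum()
    return float(np.sqrt(d2))


def run_transient(initial_state: State, mesh: Mesh, params: ModelParams,
                  boundary: BoundaryData | None,
                  config: SolverConfig) -> TransientResult:
    """March in time until ``max_steps`` or until the weighted L2 distance of
    consecutive states drops below ``steady_tol``.

    When the drift is active the initial potential is recomputed from the
    Poisson equation with the initial concentrations as charge density.
    """
    state = initial_state.copy()
    if params.drift_enabled:
        state.phi = assemble_poisson(state.u, mesh, params, boundary)
    trajectory = [state]
    records = [diag.make_record(state, mesh, params, newton_iterations=0)]
    reached = False
    for step in range(1, config.max_steps + 1):
        res = advance_time_step(state, mesh, params, boundary, config)
        if not res.converged:
            raise NewtonFailure(
                f"Newton did not converge at step {step} "
                f"(residual {res.residual_norm:.3e})",
                step=step,
                history=res.residual_history,
            )
        new_state = res.state
        if config.store_trajectory:
            trajectory.append(new_state)
        else:
            trajectory = [trajectory[0], new_state]
        if step % config.record_every == 0:
            records.append(
                diag.make_record(new_state, mesh, params,
                                 newton_iterations=res.iterations)
            )
        dn = _state_difference_norm(new_state, state, mesh)
        state = new_state
        if dn < config.steady_tol:
            reached = True
            break
    return TransientResult(trajectory, records, state.k, reached)


def solve_steady(mesh: Mesh, params: ModelParams,
                 boundary: BoundaryData | None, config: SolverConfig,
                 initial_state: State | None = None) -> State:
    """Steady state determined from the boundary data.

    All-Neumann with the drift off: the constant state carrying the initial
    masses (returned analytically; mass is conserved and the entropy decays to
    its minimum over states of fixed mass).  Otherwise the transient is run to
    the steady threshold.
    """
    n_dir = len(mesh.dirichlet_edges)
    if n_dir == 0 and not params.drift_enabled:
        if initial_state is None:
            raise ValueError("all-Neumann steady state needs initial masses")
        means = (mesh.cell_measures[None, :] * initial_state.u).sum(axis=1) / mesh.area
        u = np.repeat(means[:, None], mesh.n_cells, axis=1)
        return State(u, np.zeros(mesh.n_cells), 0)
    if initial_state is None:
        if n_dir == 0:
            raise ValueError("need Dirichlet data or an initial state")
        means = boundary.u_bar.mean(axis=1)
        u = np.repeat(means[:, None], mesh.n_cells, axis=1)
        initial_state = State(u, np.zeros(mesh.n_cells), 0)
    result = run_transient(initial_state, mesh, params, boundary, config)
    if not result.reached_steady:
        raise NewtonFailure(
            f"steady state not reached within {config.max_steps} steps "
            f"(threshold {config.steady_tol:g})"
        )
    return result.final
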