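"""Built-in problems: the 2D calcium-selective channel, verification problems
with known behaviour, and random admissible fixtures.

The channel scenario models a calcium-selective ion channel connecting two
reservoirs.  Selectivity comes from confined oxygen ions (O^1/2-) fixed
inside the channel region: they contribute the permanent charge density
f = -u_ox/2 in the Poisson equation and occupy volume, u_0 = 1 - sum_i u_i -
u_ox.  Three mobile species are tracked: Ca2+ (z=2), Na+ (z=1), Cl- (z=-1).
The scaled maximal oxygen fraction is u_ox,max = (N_A / u_typ) * 52 mol/L
with Avogadro's constant N_A = 6.022e23 / mol and the typical concentration
u_typ = 3.7037e25 / L, giving u_ox,max ~ 0.84.

Only the oxygen-profile breakpoints (plateau on [0.45, 0.55], linear ramps on
[0.35, 0.45] and [0.55, 0.65]) and the disc radius 0.03 are fixed by the
model; the channel cross-section and the reservoir Dirichlet values are
geometry/configuration choices, with illustrative defaults chosen small
enough that the volume constraint holds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    Mesh,
    build_acute_triangular_mesh,
    build_rectangular_mesh,
    mesh_from_cells,
)
from .scheme import BoundaryData, ModelParams, State, assemble_poisson
from .solver import SolverConfig

__all__ = [
    "AVOGADRO",
    "TYPICAL_CONCENTRATION",
    "oxygen_scaling_constant",
    "ChannelConfig",
    "ProblemSpec",
    "oxygen_profile",
    "make_channel_problem",
    "make_heat_limit_problem",
    "random_admissible_state",
    "exact_heat_solution",
]

AVOGADRO = 6.022e23           # 1/mol
TYPICAL_CONCENTRATION = 3.7037e25  # 1/L


def oxygen_scaling_constant(molarity: float = 52.0) -> float:
    """Scaled maximal oxygen fraction (N_A / u_typ) * molarity, ~0.84 at the
    default 52 mol/L."""
    return AVOGADRO / TYPICAL_CONCENTRATION * molarity


@dataclass
class ProblemSpec:
    """A ready-to-run bundle: mesh, parameters, boundary data, initial state
    and solver configuration, mutually consistent."""

    mesh: Mesh
    params: ModelParams
    boundary: BoundaryData
    initial_state: State
    config: SolverConfig


def _default_disc_centers() -> np.ndarray:
    # eight confined oxygen ions inside the channel region
    xs = np.linspace(0.44, 0.56, 4)
    ys = np.array([0.46, 0.54])
    return np.array([(x, y) for y in ys for x in xs])


@dataclass
class ChannelConfig:
    """Geometry and data of the calcium-channel scenario.

    The domain is an H-shape inside the unit square: two reservoirs
    (x < 0.35 and x > 0.65, full height) joined by a channel of half-height
    ``channel_half_height`` centered at y = 0.5 spanning 0.35 <= x <= 0.65.
    """

    u_ox_max: float = field(default_factory=oxygen_scaling_constant)
    oxygen_mode: str = "linear"             # "linear" | "discs"
    disc_radius: float = 0.03
    disc_centers: np.ndarray = field(default_factory=_default_disc_centers)
    channel_half_height: float = 0.125
    nx: int = 40                            # cells per unit length (multiple of 40)
    mesh_type: str = "rectangular"          # "rectangular" | "triangular"
    z: tuple = (2.0, 1.0, -1.0)             # Ca2+, Na+, Cl-
    D: tuple = (1.0, 1.0, 1.0)
    beta: float = 1.0
    lam2: float = 4.68e-4
    # illustrative electroneutral reservoir traces (2*Ca + Na - Cl = 0)
    u_left: tuple = (0.02, 0.04, 0.08)
    u_right: tuple = (0.01, 0.02, 0.04)
    phi_left: float = 0.0
    phi_right: float = 0.0
    dt: float = 1e-3
    max_steps: int = 2000

    def __post_init__(self):
        if not (0.0 < self.u_ox_max < 1.0):
            raise ValueError("u_ox_max must lie in (0, 1)")
        if self.disc_radius <= 0:
            raise ValueError("disc radius must be positive")
        if self.lam2 <= 0:
            raise ValueError("lambda^2 must be positive")


def oxygen_profile(x, y, config: ChannelConfig) -> np.ndarray:
    """Scaled oxygen fraction at (x, y).

    Linear mode (y-independent):
        u_ox,max        for 0.45 <= x <= 0.55,
        u_ox,max*10(x - 0.35)   on the left ramp  [0.35, 0.45],
        u_ox,max*10(0.65 - x)   on the right ramp [0.55, 0.65],
        0 elsewhere.
    Disc mode: u_ox,max inside any fixed disc, 0 outside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if config.oxygen_mode == "linear":
        ramp_l = 10.0 * (x - 0.35)
        ramp_r = 10.0 * (0.65 - x)
        prof = np.where(
            (x >= 0.45) & (x <= 0.55), 1.0,
            np.where((x >= 0.35) & (x < 0.45), ramp_l,
                     np.where((x > 0.55) & (x <= 0.65), ramp_r, 0.0)),
        )
        return config.u_ox_max * prof * np.ones_like(y)
    if config.oxygen_mode == "discs":
        inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for cx, cy in np.asarray(config.disc_centers):
            inside |= (x - cx) ** 2 + (y - cy) ** 2 <= config.disc_radius**2
        return np.where(inside, config.u_ox_max, 0.0)
    raise ValueError(f"unknown oxygen mode {config.oxygen_mode!r}")


def _h_shape_mask(centers: np.ndarray, half_height: float) -> np.ndarray:
    x, y = centers[:, 0], centers[:, 1]
    in_reservoir = (x < 0.35) | (x > 0.65)
    in_channel = np.abs(y - 0.5) < half_height
    return in_reservoir | in_channel


def _submesh(mesh: Mesh, keep: np.ndarray) -> Mesh:
    cells = mesh.cells[keep]
    used = np.unique(cells)
    remap = -np.ones(len(mesh.nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return mesh_from_cells(mesh.nodes[used], remap[cells], mesh.cell_shape)


def make_channel_problem(config: ChannelConfig | None = None) -> ProblemSpec:
    """Assemble the channel scenario.

    Dirichlet data on the two reservoir ends (x = 0 and x = 1), no-flux
    elsewhere; initial ion concentrations interpolate linearly in x between
    the reservoir traces; the initial potential is computed from the Poisson
    equation with the initial charge.
    """
    config = config or ChannelConfig()
    if config.nx % 40 != 0:
        raise ValueError("nx must be a multiple of 40 so the geometry is resolved")
    hh = config.channel_half_height
    if abs(hh * config.nx - round(hh * config.nx)) > 1e-9:
        raise ValueError("channel_half_height must align with the grid")

    if config.mesh_type == "rectangular":
        base = build_rectangular_mesh(config.nx, config.nx)
    elif config.mesh_type == "triangular":
        base = build_acute_triangular_mesh(config.nx, config.nx)
    else:
        raise ValueError(f"unknown mesh type {config.mesh_type!r}")
    keep = _h_shape_mask(base.cell_centers, hh)
    mesh = _submesh(base, keep)
    mesh.set_boundary_tags(
        lambda mids: (mids[:, 0] < 1e-12) | (mids[:, 0] > 1 - 1e-12)
    )

    xc, yc = mesh.cell_centers[:, 0], mesh.cell_centers[:, 1]
    u_ox = oxygen_profile(xc, yc, config)
    f = -0.5 * u_ox

    n = 3
    params = ModelParams(
        n=n,
        D=np.asarray(config.D, dtype=float),
        z=np.asarray(config.z, dtype=float),
        beta=config.beta,
        lam2=config.lam2,
        f=f,
        u_static=u_ox,
        drift_enabled=True,
        truncation_enabled=True,
    )

    uL = np.asarray(config.u_left, dtype=float)
    uR = np.asarray(config.u_right, dtype=float)
    u0_init = uL[:, None] * (1.0 - xc)[None, :] + uR[:, None] * xc[None, :]
    if np.any(u0_init.sum(axis=0) + u_ox > 1.0):
        raise ValueError(
            "initial state inadmissible: sum_i u_i + u_ox > 1 somewhere; "
            "lower the reservoir concentrations or u_ox_max"
        )

    dir_edges = mesh.dirichlet_edges
    mids = mesh.edge_midpoints[dir_edges]
    left = mids[:, 0] < 0.5
    u_bar = np.where(left[None, :], uL[:, None], uR[:, None])
    phi_bar = np.where(left, config.phi_left, config.phi_right)
    ox_bar = oxygen_profile(mids[:, 0], mids[:, 1], config)
    boundary = BoundaryData(u_bar, phi_bar, u_static_bar=ox_bar)

    state = State(u0_init, np.zeros(mesh.n_cells), 0)
    state.phi = assemble_poisson(state.u, mesh, params, boundary)

    solver = SolverConfig(dt=config.dt, max_steps=config.max_steps,
                          damping=True)
    return ProblemSpec(mesh, params, boundary, state, solver)


def make_heat_limit_problem(nx: int, amplitude: float = 0.25,
                            dt: float = 1e-4, max_steps: int = 1000) -> ProblemSpec:
    """Single uncharged species, no drift: the scheme's continuum limit is the
    heat equation.  Unit square, all-Neumann, initial data the exact cell
    average of 0.5 + amplitude * cos(pi x)."""
    if amplitude > 0.5 or amplitude < 0:
        raise ValueError("amplitude must lie in [0, 0.5] for admissibility")
    mesh = build_rectangular_mesh(nx, nx)
    params = ModelParams(n=1, D=[1.0], z=[0.0], drift_enabled=False,
                         truncation_enabled=False)
    h = 1.0 / nx
    xc = mesh.cell_centers[:, 0]
    xl, xr = xc - h / 2, xc + h / 2
    avg = 0.5 + amplitude * (np.sin(np.pi * xr) - np.sin(np.pi * xl)) / (np.pi * h)
    state = State(avg[None, :], np.zeros(mesh.n_cells), 0)
    boundary = BoundaryData.empty(1)
    config = SolverConfig(dt=dt, max_steps=max_steps)
    return ProblemSpec(mesh, params, boundary, state, config)


def exact_heat_solution(x, t, amplitude: float = 0.25, D: float = 1.0):
    """Continuum-limit solution 0.5 + a e^{-D pi^2 t} cos(pi x) of the
    single-species drift-free system on the unit square."""
    return 0.5 + amplitude * np.exp(-D * np.pi**2 * t) * np.cos(np.pi * np.asarray(x))


def random_admissible_state(mesh: Mesh, n: int, seed: int,
                            scale: float = 0.95) -> State:
    """Strictly admissible random state: per cell, (u_1..u_n) is a uniform
    draw from the open simplex scaled by ``scale`` < 1, so u_i > 0 and
    sum_i u_i < 1 strictly.  Reproducible under the seed."""
    if n < 1:
        raise ValueError("need n >= 1")
    if not (0 < scale < 1):
        raise ValueError("scale must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    simplex = rng.dirichlet(np.ones(n + 1), size=mesh.n_cells)  # (Nc, n+1)
    u = scale * simplex[:, :n].T
    return State(u, np.zeros(mesh.n_cells), 0)
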