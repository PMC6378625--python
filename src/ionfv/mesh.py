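"""Admissible two-point finite-volume meshes.

A mesh is *admissible* when, for every internal edge sigma = K|L, the segment
joining the cell centers x_K and x_L is orthogonal to sigma.  Two families are
provided: axis-aligned rectangular meshes (centers = centroids) and structured
strictly-acute triangulations (centers = circumcenters, which acuteness keeps
strictly inside each triangle).  Both support regular nested refinement, which
the L1 convergence study relies on.

All per-edge geometric quantities used by the scheme live here:

* ``m(sigma)``   edge length,
* ``d_sigma``    distance between the two centers (internal) or from the
  center to the edge (exterior),
* ``tau_sigma = m(sigma)/d_sigma``  the transmissibility,
* ``m(T_KL) = m(sigma) d_sigma / 2``  the diamond (dual) cell area in 2D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INTERNAL",
    "DIRICHLET",
    "NEUMANN",
    "Mesh",
    "Edge",
    "MeshQualityReport",
    "build_rectangular_mesh",
    "build_acute_triangular_mesh",
    "mesh_from_cells",
    "refine_mesh",
    "compute_edge_geometry",
    "check_admissibility",
    "read_mesh",
    "write_mesh",
]

INTERNAL = 0
DIRICHLET = 1
NEUMANN = 2

_TAG_NAMES = {INTERNAL: "internal", DIRICHLET: "dirichlet", NEUMANN: "neumann"}


@dataclass
class Edge:
    """Read-only view of one edge of a :class:`Mesh`."""

    index: int
    kind: int
    cells: tuple  # (K,) exterior or (K, L) internal
    measure: float
    d: float
    tau: float
    normal: np.ndarray  # unit, oriented K -> L (internal) or outward (exterior)
    dual_measure: float
    nodes: np.ndarray  # (2, 2) endpoint coordinates


@dataclass
class MeshQualityReport:
    admissible: bool
    zeta: float
    max_orthogonality_deviation: float
    h_max: float


@dataclass
class Mesh:
    """2D polygonal mesh with two-point flux geometry.

    ``cells`` holds node indices (counter-clockwise); triangles and
    axis-aligned rectangles are supported.  ``edge_cells[:, 1] == -1`` marks
    exterior edges.  ``parent`` maps each cell to the cell of the mesh it was
    refined from (or ``None`` for a root mesh).
    """

    nodes: np.ndarray
    cells: np.ndarray
    cell_shape: str  # "triangle" | "rectangle"
    cell_centers: np.ndarray
    cell_measures: np.ndarray
    edge_nodes: np.ndarray
    edge_cells: np.ndarray
    edge_kind: np.ndarray
    edge_measure: np.ndarray = field(default=None, repr=False)
    edge_d: np.ndarray = field(default=None, repr=False)
    edge_tau: np.ndarray = field(default=None, repr=False)
    edge_normal: np.ndarray = field(default=None, repr=False)
    edge_dual_measure: np.ndarray = field(default=None, repr=False)
    parent: np.ndarray | None = None

    dim = 2

    # -- basic queries -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_measures)

    @property
    def n_edges(self) -> int:
        return len(self.edge_kind)

    @property
    def area(self) -> float:
        return float(self.cell_measures.sum())

    @property
    def internal_edges(self) -> np.ndarray:
        return np.nonzero(self.edge_kind == INTERNAL)[0]

    @property
    def dirichlet_edges(self) -> np.ndarray:
        return np.nonzero(self.edge_kind == DIRICHLET)[0]

    @property
    def neumann_edges(self) -> np.ndarray:
        return np.nonzero(self.edge_kind == NEUMANN)[0]

    @property
    def edge_midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.edge_nodes[:, 0]] + self.nodes[self.edge_nodes[:, 1]])

    @property
    def h_max(self) -> float:
        pts = self.nodes[self.cells]  # (Nc, nv, 2)
        nv = pts.shape[1]
        d2 = 0.0
        for a in range(nv):
            for b in range(a + 1, nv):
                d2 = np.maximum(d2, ((pts[:, a] - pts[:, b]) ** 2).sum(axis=1))
        return float(np.sqrt(np.max(d2)))

    def edge(self, e: int) -> Edge:
        K, L = self.edge_cells[e]
        cells = (int(K),) if L < 0 else (int(K), int(L))
        return Edge(
            index=e,
            kind=int(self.edge_kind[e]),
            cells=cells,
            measure=float(self.edge_measure[e]),
            d=float(self.edge_d[e]),
            tau=float(self.edge_tau[e]),
            normal=self.edge_normal[e].copy(),
            dual_measure=float(self.edge_dual_measure[e]),
            nodes=self.nodes[self.edge_nodes[e]].copy(),
        )

    # -- boundary tagging --------------------------------------------------
    def set_boundary_tags(self, dirichlet_predicate) -> "Mesh":
        """Tag exterior edges Dirichlet where the predicate holds at their
        midpoint; the rest stay/become Neumann."""
        ext = self.edge_cells[:, 1] < 0
        mids = self.edge_midpoints
        dir_mask = np.zeros(self.n_edges, dtype=bool)
        dir_mask[ext] = np.asarray(dirichlet_predicate(mids[ext]), dtype=bool)
        self.edge_kind = np.where(
            ext, np.where(dir_mask, DIRICHLET, NEUMANN), INTERNAL
        ).astype(np.int8)
        return self


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _polygon_measures(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    pts = nodes[cells]
    x, y = pts[..., 0], pts[..., 1]
    xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    return 0.5 * np.abs((x * yn - xn * y).sum(axis=1))


def _circumcenters(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    a, b, c = nodes[cells[:, 0]], nodes[cells[:, 1]], nodes[cells[:, 2]]
    ab, ac = b - a, c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    if np.any(np.abs(d) < 1e-300):
        raise ValueError("degenerate triangle encountered")
    ab2 = (ab**2).sum(axis=1)
    ac2 = (ac**2).sum(axis=1)
    ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
    uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    return a + np.stack([ux, uy], axis=1)


def mesh_from_cells(
    nodes: np.ndarray,
    cells: np.ndarray,
    cell_shape: str,
    centers: np.ndarray | None = None,
    parent: np.ndarray | None = None,
) -> Mesh:
    """Assemble a :class:`Mesh` from nodes and cell connectivity.

    Centers default to circumcenters for triangles and centroids for
    rectangles.  Exterior edges are tagged Neumann; retag with
    :meth:`Mesh.set_boundary_tags`.
    """
    nodes = np.asarray(nodes, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    if cell_shape not in ("triangle", "rectangle"):
        raise ValueError(f"unsupported cell shape: {cell_shape!r}")
    nv = cells.shape[1]
    if (cell_shape == "triangle") != (nv == 3):
        raise ValueError("cell connectivity does not match cell shape")

    measures = _polygon_measures(nodes, cells)
    if np.any(measures <= 0):
        raise ValueError("cell with non-positive area")
    if centers is None:
        if cell_shape == "triangle":
            centers = _circumcenters(nodes, cells)
        else:
            centers = nodes[cells].mean(axis=1)
    else:
        centers = np.asarray(centers, dtype=float)

    # unique edges from sorted node pairs
    raw = np.stack(
        [cells, np.roll(cells, -1, axis=1)], axis=2
    ).reshape(-1, 2)  # (Nc*nv, 2)
    raw_sorted = np.sort(raw, axis=1)
    edge_nodes, inv = np.unique(raw_sorted, axis=0, return_inverse=True)
    n_edges = len(edge_nodes)
    owner = np.repeat(np.arange(len(cells)), nv)

    counts = np.bincount(inv, minlength=n_edges)
    if np.any(counts > 2):
        raise ValueError("edge shared by more than two cells")
    edge_cells = np.full((n_edges, 2), -1, dtype=np.int64)
    order = np.argsort(inv, kind="stable")
    seen_first = np.zeros(n_edges, dtype=bool)
    for idx in order:
        e = inv[idx]
        if not seen_first[e]:
            edge_cells[e, 0] = owner[idx]
            seen_first[e] = True
        else:
            edge_cells[e, 1] = owner[idx]
    edge_kind = np.where(edge_cells[:, 1] < 0, NEUMANN, INTERNAL).astype(np.int8)

    mesh = Mesh(
        nodes=nodes,
        cells=cells,
        cell_shape=cell_shape,
        cell_centers=centers,
        cell_measures=measures,
        edge_nodes=edge_nodes,
        edge_cells=edge_cells,
        edge_kind=edge_kind,
        parent=None if parent is None else np.asarray(parent, dtype=np.int64),
    )
    return compute_edge_geometry(mesh)


def compute_edge_geometry(mesh: Mesh) -> Mesh:
    """Fill m(sigma), d_sigma, tau_sigma, unit normals and dual measures."""
    p0 = mesh.nodes[mesh.edge_nodes[:, 0]]
    p1 = mesh.nodes[mesh.edge_nodes[:, 1]]
    tvec = p1 - p0
    m_sigma = np.sqrt((tvec**2).sum(axis=1))
    if np.any(m_sigma <= 0):
        raise ValueError("zero-length edge")
    that = tvec / m_sigma[:, None]
    # exact edge normal (rotate tangent by 90 degrees)
    nhat = np.stack([that[:, 1], -that[:, 0]], axis=1)

    mid = 0.5 * (p0 + p1)
    K = mesh.edge_cells[:, 0]
    L = mesh.edge_cells[:, 1]
    interior = L >= 0

    xK = mesh.cell_centers[K]
    d = np.empty(mesh.n_edges)
    # orient normal from K towards the edge / the neighbour
    to_mid = ((mid - xK) * nhat).sum(axis=1)
    sign = np.where(to_mid >= 0, 1.0, -1.0)
    nhat *= sign[:, None]

    if np.any(interior):
        xL = mesh.cell_centers[L[interior]]
        d[interior] = np.sqrt(((xL - xK[interior]) ** 2).sum(axis=1))
    ext = ~interior
    # distance from x_K to the line supporting the edge
    d[ext] = np.abs(((mid - xK) * nhat).sum(axis=1))[ext]
    if np.any(d <= 1e-14 * max(1.0, float(m_sigma.max()))):
        raise ValueError(
            "coincident cell centers / center on edge: d_sigma = 0 "
            "(mesh not admissible)"
        )

    mesh.edge_measure = m_sigma
    mesh.edge_d = d
    mesh.edge_tau = m_sigma / d
    mesh.edge_normal = nhat
    dual = np.zeros(mesh.n_edges)
    dual[interior] = 0.5 * m_sigma[interior] * d[interior]
    mesh.edge_dual_measure = dual
    return mesh


def check_admissibility(mesh: Mesh, orthogonality_tol: float = 1e-10) -> MeshQualityReport:
    """Orthogonality of center segments to edges and the regularity constant.

    ``zeta = min d(x_K, sigma) / d_sigma`` over all cell/edge incidences; a
    mesh is admissible when every internal center segment is orthogonal to its
    edge (within ``orthogonality_tol`` radians), the centers lie on the
    correct sides, and ``zeta > 0``.
    """
    p0 = mesh.nodes[mesh.edge_nodes[:, 0]]
    p1 = mesh.nodes[mesh.edge_nodes[:, 1]]
    tvec = p1 - p0
    that = tvec / np.sqrt((tvec**2).sum(axis=1))[:, None]
    mid = 0.5 * (p0 + p1)

    K = mesh.edge_cells[:, 0]
    L = mesh.edge_cells[:, 1]
    interior = L >= 0
    nhat = mesh.edge_normal

    worst_dev = 0.0
    zeta = np.inf
    ok = True
    if np.any(interior):
        xK = mesh.cell_centers[K[interior]]
        xL = mesh.cell_centers[L[interior]]
        seg = xL - xK
        dlen = np.sqrt((seg**2).sum(axis=1))
        # deviation of the center segment from the edge normal direction
        sin_dev = np.abs((seg * that[interior]).sum(axis=1)) / dlen
        dev = np.arcsin(np.clip(sin_dev, 0.0, 1.0))
        worst_dev = float(dev.max())
        if worst_dev >= orthogonality_tol:
            ok = False
        # signed distances of both centers to the edge line
        sK = ((mid[interior] - xK) * nhat[interior]).sum(axis=1)
        sL = -((mid[interior] - xL) * nhat[interior]).sum(axis=1)
        if np.any(sK <= 0) or np.any(sL <= 0):
            ok = False
            zeta = 0.0
        else:
            zeta = float(min(np.min(sK / dlen), np.min(sL / dlen)))
    ext = ~interior
    if np.any(ext):
        # d(x_K, sigma) = d_sigma on exterior edges by definition
        zeta = min(zeta, 1.0)
    if not np.isfinite(zeta):  # single cell, no edges at all cannot happen
        zeta = 1.0
    if zeta <= 0:
        ok = False
    return MeshQualityReport(
        admissible=ok,
        zeta=zeta,
        max_orthogonality_deviation=worst_dev,
        h_max=mesh.h_max,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _check_domain(domain):
    (x0, y0), (x1, y1) = domain
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate domain: zero width or height")
    return float(x0), float(y0), float(x1), float(y1)


def build_rectangular_mesh(nx: int, ny: int, domain=((0.0, 0.0), (1.0, 1.0))) -> Mesh:
    """Uniform nx-by-ny rectangular mesh; centers are centroids."""
    if nx < 1 or ny < 1:
        raise ValueError("nx, ny must be >= 1")
    x0, y0, x1, y1 = _check_domain(domain)
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    j, i = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    n00 = j * (nx + 1) + i
    cells = np.stack(
        [n00, n00 + 1, n00 + nx + 2, n00 + nx + 1], axis=2
    ).reshape(-1, 4)
    return mesh_from_cells(nodes, cells, "rectangle")


# Strictly acute 8-triangle pattern for one rectangle:
# corners A B C D, edge midpoints Mb (bottom) and Mt (top), and two interior
# vertices P1, P2 placed symmetrically about the vertical midline.  Every
# triangle is strictly acute for aspect ratios around 1 (verified at build
# time), so circumcenters are strictly interior and the mesh is admissible.
_ACUTE_PATTERN_TRIS = np.array(
    [
        [6, 3, 0],  # (P1, D, A)
        [2, 7, 1],  # (C, P2, B)
        [4, 6, 0],  # (Mb, P1, A)
        [4, 7, 6],  # (Mb, P2, P1)
        [7, 4, 1],  # (P2, Mb, B)
        [7, 5, 6],  # (P2, Mt, P1)
        [6, 5, 3],  # (P1, Mt, D)
        [5, 7, 2],  # (Mt, P2, C)
    ],
    dtype=np.int64,
)


def _acute_pattern_params(aspect: float) -> tuple[float, float]:
    """Interior-vertex placement (d, y) minimising the largest angle of the
    8-triangle pattern on a unit-width rectangle of the given height/width
    aspect.  Deterministic coarse-to-fine grid search."""
    def max_angle(dd, yy):
        V = _pattern_vertices(dd, yy, aspect)
        worst = 0.0
        for f in _ACUTE_PATTERN_TRIS:
            p = V[f]
            for i in range(3):
                u = p[(i + 1) % 3] - p[i]
                v = p[(i + 2) % 3] - p[i]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                worst = max(worst, np.arccos(np.clip(c, -1.0, 1.0)))
        return worst

    best = (np.inf, 0.05, 0.5)
    d_grid = np.linspace(0.02, 0.20, 19)
    y_grid = np.linspace(0.08, 0.92, 43)
    for dd in d_grid:
        for yy in y_grid:
            a = max_angle(dd, yy)
            if a < best[0]:
                best = (a, dd, yy)
    # local refinement
    _, dd, yy = best
    for scale in (0.02, 0.004):
        dl = np.linspace(max(dd - scale, 1e-3), dd + scale, 11)
        yl = np.linspace(max(yy - scale, 1e-3), min(yy + scale, 0.99), 11)
        for d2 in dl:
            for y2 in yl:
                a = max_angle(d2, y2)
                if a < best[0]:
                    best = (a, d2, y2)
        _, dd, yy = best
    if best[0] >= 0.5 * np.pi - 1e-6:
        raise ValueError(
            f"no strictly acute pattern for cell aspect ratio {aspect:.3g}; "
            "choose nx, ny giving cells closer to square"
        )
    return best[1], best[2]


def _pattern_vertices(d: float, y: float, aspect: float) -> np.ndarray:
    V = np.array(
        [
            (0.0, 0.0),
            (1.0, 0.0),
            (1.0, 1.0),
            (0.0, 1.0),
            (0.5, 0.0),
            (0.5, 1.0),
            (0.5 - d, y),
            (0.5 + d, y),
        ]
    )
    V[:, 1] *= aspect
    return V


def build_acute_triangular_mesh(nx: int, ny: int, domain=((0.0, 0.0), (1.0, 1.0))) -> Mesh:
    """Structured strictly-acute triangulation: 8 acute triangles per
    rectangular subcell.  Raises if the subcell aspect ratio admits no acute
    pattern."""
    if nx < 1 or ny < 1:
        raise ValueError("nx, ny must be >= 1")
    x0, y0, x1, y1 = _check_domain(domain)
    w = (x1 - x0) / nx
    h = (y1 - y0) / ny
    d, yint = _acute_pattern_params(h / w)

    nodes_list = []
    cells_list = []
    node_index: dict[tuple[int, int], int] = {}

    def get_node(key, xy):
        if key not in node_index:
            node_index[key] = len(nodes_list)
            nodes_list.append(xy)
        return node_index[key]

    for j in range(ny):
        for i in range(nx):
            ox, oy = x0 + i * w, y0 + j * h
            # shared lattice keys: corners (2i, 2j scale), edge midpoints
            keys = [
                ("g", 2 * i, 2 * j),
                ("g", 2 * i + 2, 2 * j),
                ("g", 2 * i + 2, 2 * j + 2),
                ("g", 2 * i, 2 * j + 2),
                ("g", 2 * i + 1, 2 * j),
                ("g", 2 * i + 1, 2 * j + 2),
                ("p", i, j, 0),
                ("p", i, j, 1),
            ]
            coords = [
                (ox, oy),
                (ox + w, oy),
                (ox + w, oy + h),
                (ox, oy + h),
                (ox + 0.5 * w, oy),
                (ox + 0.5 * w, oy + h),
                (ox + (0.5 - d) * w, oy + yint * h),
                (ox + (0.5 + d) * w, oy + yint * h),
            ]
            ids = [get_node(k, c) for k, c in zip(keys, coords)]
            for tri in _ACUTE_PATTERN_TRIS:
                cells_list.append([ids[tri[0]], ids[tri[1]], ids[tri[2]]])

    nodes = np.array(nodes_list)
    cells = np.array(cells_list, dtype=np.int64)
    mesh = mesh_from_cells(nodes, cells, "triangle")
    _reject_non_acute(mesh)
    return mesh


def _reject_non_acute(mesh: Mesh) -> None:
    pts = mesh.nodes[mesh.cells]
    for i in range(3):
        u = pts[:, (i + 1) % 3] - pts[:, i]
        v = pts[:, (i + 2) % 3] - pts[:, i]
        dots = (u * v).sum(axis=1)
        if np.any(dots <= 0):
            raise ValueError("triangulation contains a non-acute triangle")


def refine_mesh(mesh: Mesh) -> Mesh:
    """Regular nested refinement: every cell splits into 4 similar cells.

    Triangles split at edge midpoints; rectangles into four equal quarters.
    The returned mesh carries ``parent`` indices into ``mesh`` and inherits
    boundary tags by midpoint lookup.
    """
    nodes = mesh.nodes
    cells = mesh.cells
    if mesh.cell_shape == "triangle":
        a, b, c = cells[:, 0], cells[:, 1], cells[:, 2]
        pab = 0.5 * (nodes[a] + nodes[b])
        pbc = 0.5 * (nodes[b] + nodes[c])
        pca = 0.5 * (nodes[c] + nodes[a])
        extra = np.concatenate([pab, pbc, pca], axis=0)
        all_nodes, new_ids = _merge_nodes(nodes, extra)
        n0 = len(nodes)
        nc = len(cells)
        mab = new_ids[np.arange(nc)]
        mbc = new_ids[np.arange(nc) + nc]
        mca = new_ids[np.arange(nc) + 2 * nc]
        A, B, C = a, b, c
        new_cells = np.concatenate(
            [
                np.stack([A, mab, mca], axis=1),
                np.stack([mab, B, mbc], axis=1),
                np.stack([mca, mbc, C], axis=1),
                np.stack([mab, mbc, mca], axis=1),
            ],
            axis=0,
        )
        parent = np.tile(np.arange(nc), 4)
    elif mesh.cell_shape == "rectangle":
        a, b, c, d = cells[:, 0], cells[:, 1], cells[:, 2], cells[:, 3]
        pab = 0.5 * (nodes[a] + nodes[b])
        pbc = 0.5 * (nodes[b] + nodes[c])
        pcd = 0.5 * (nodes[c] + nodes[d])
        pda = 0.5 * (nodes[d] + nodes[a])
        pmid = 0.25 * (nodes[a] + nodes[b] + nodes[c] + nodes[d])
        extra = np.concatenate([pab, pbc, pcd, pda, pmid], axis=0)
        all_nodes, new_ids = _merge_nodes(nodes, extra)
        nc = len(cells)
        idx = np.arange(nc)
        mab = new_ids[idx]
        mbc = new_ids[idx + nc]
        mcd = new_ids[idx + 2 * nc]
        mda = new_ids[idx + 3 * nc]
        mid = new_ids[idx + 4 * nc]
        new_cells = np.concatenate(
            [
                np.stack([a, mab, mid, mda], axis=1),
                np.stack([mab, b, mbc, mid], axis=1),
                np.stack([mid, mbc, c, mcd], axis=1),
                np.stack([mda, mid, mcd, d], axis=1),
            ],
            axis=0,
        )
        parent = np.tile(np.arange(nc), 4)
    else:  # pragma: no cover
        raise ValueError(f"unsupported cell shape: {mesh.cell_shape!r}")

    # order the children spatially (lexicographic by centroid): the naive
    # child-block ordering scatters the sparsity pattern and slows the
    # direct factorization of the implicit systems dramatically
    cent = all_nodes[new_cells].mean(axis=1)
    order = np.lexsort((cent[:, 0], cent[:, 1]))
    fine = mesh_from_cells(all_nodes, new_cells[order], mesh.cell_shape,
                           parent=parent[order])
    _inherit_boundary_tags(mesh, fine)
    return fine


def _merge_nodes(nodes: np.ndarray, extra: np.ndarray):
    """Append new points, merging duplicates (shared edge midpoints)."""
    scale = max(1.0, float(np.abs(nodes).max()))
    key = np.round(extra / (1e-12 * scale)).astype(np.int64)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    # representative coordinates for each unique key
    rep = np.zeros((len(uniq), 2))
    rep[inv] = extra
    all_nodes = np.concatenate([nodes, rep], axis=0)
    new_ids = len(nodes) + inv
    return all_nodes, new_ids


def _inherit_boundary_tags(coarse: Mesh, fine: Mesh) -> None:
    ext = fine.edge_cells[:, 1] < 0
    if not np.any(ext):
        return
    c_ext = coarse.edge_cells[:, 1] < 0
    if not np.any(c_ext):
        return
    c_idx = np.nonzero(c_ext)[0]
    p0 = coarse.nodes[coarse.edge_nodes[c_idx, 0]]
    p1 = coarse.nodes[coarse.edge_nodes[c_idx, 1]]
    mids = fine.edge_midpoints[ext]
    # find the coarse exterior edge containing each fine exterior midpoint
    tags = np.full(mids.shape[0], NEUMANN, dtype=np.int8)
    tvec = p1 - p0
    tlen2 = (tvec**2).sum(axis=1)
    for i, m in enumerate(mids):
        r = m[None, :] - p0
        t = (r * tvec).sum(axis=1) / tlen2
        perp = r - t[:, None] * tvec
        on = (np.abs(perp).max(axis=1) < 1e-10) & (t > -1e-10) & (t < 1 + 1e-10)
        j = np.nonzero(on)[0]
        if len(j):
            tags[i] = coarse.edge_kind[c_idx[j[0]]]
    fine.edge_kind[ext] = tags


def ancestor_indices(meshes: list[Mesh]) -> np.ndarray:
    """Map each cell of ``meshes[-1]`` to its ancestor cell in ``meshes[0]``
    along a chain of nested refinements."""
    if len(meshes) < 1:
        raise ValueError("need at least one mesh")
    anc = np.arange(meshes[-1].n_cells)
    for m in reversed(meshes[1:]):
        if m.parent is None:
            raise ValueError("meshes are not a nested refinement chain")
        anc = m.parent[anc]
    return anc


# ---------------------------------------------------------------------------
# plain-text mesh file format (JSON)
# ---------------------------------------------------------------------------

def write_mesh(mesh: Mesh, path) -> None:
    """Write the mesh as a small JSON document (nodes, cells, boundary tags)."""
    ext = np.nonzero(mesh.edge_cells[:, 1] < 0)[0]
    payload = {
        "cell_shape": mesh.cell_shape,
        "nodes": mesh.nodes.tolist(),
        "cells": mesh.cells.tolist(),
        "boundary": [
            [int(mesh.edge_nodes[e, 0]), int(mesh.edge_nodes[e, 1]),
             _TAG_NAMES[int(mesh.edge_kind[e])]]
            for e in ext
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_mesh(path) -> Mesh:
    with open(path) as fh:
        payload = json.load(fh)
    mesh = mesh_from_cells(
        np.asarray(payload["nodes"], dtype=float),
        np.asarray(payload["cells"], dtype=np.int64),
        payload["cell_shape"],
    )
    tag_of = {}
    for n0, n1, name in payload.get("boundary", []):
        rev = {v: k for k, v in _TAG_NAMES.items()}
        tag_of[(min(n0, n1), max(n0, n1))] = rev[name]
    if tag_of:
        for e in np.nonzero(mesh.edge_cells[:, 1] < 0)[0]:
            key = (int(mesh.edge_nodes[e, 0]), int(mesh.edge_nodes[e, 1]))
            key = (min(key), max(key))
            if key in tag_of:
                mesh.edge_kind[e] = tag_of[key]
    return mesh
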