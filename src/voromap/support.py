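"""Voronoi spatial support: tessellation, adjacency graph and Besag structure matrix.

Mobile-tower locations define the spatial resolution of the analysis: each
tower's coverage area is approximated by its Voronoi cell, clipped to the
study-region boundary.  The cells become the areal units ("polygons") of a
Besag intrinsic conditional autoregressive (ICAR) model, whose graph is the
rook adjacency of the cells and whose structure matrix is the graph Laplacian
R = D - A.  Multiplied by the spatial precision tau, R forms the (improper)
ICAR precision; a sum-to-zero constraint per connected component makes the
field identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

__all__ = [
    "TowerSet",
    "PolygonSupport",
    "build_voronoi",
    "build_adjacency",
    "build_structure_matrix",
    "constrained_marginal_variances",
]

_DUP_TOL = 1e-9


@dataclass
class TowerSet:
    """Point locations (planar x/y) that seed the Voronoi tessellation."""

    points: np.ndarray  # (n, 2)
    crs_note: str = "planar"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError("need at least 2 tower points")
        # duplicate towers would produce empty Voronoi cells
        d = self.points[:, None, :] - self.points[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < _DUP_TOL:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            raise ValueError(f"duplicate tower points at indices {i} and {j}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PolygonSupport:
    """Clipped Voronoi partition plus its neighbourhood/precision structure.

    ``polygons[i]`` is the cell of ``towers.points[i]``.  ``adjacency`` holds
    rook (shared-edge) neighbour pairs (i, j), i < j.  ``structure_matrix`` is
    the sparse Laplacian R = D - A, optionally variance-scaled per connected
    component so the geometric mean of the constrained marginal variances of
    the ICAR field equals one at tau = 1.
    """

    towers: TowerSet
    polygons: list
    boundary: Polygon
    adjacency: list[tuple[int, int]] | None = None
    n_neighbours: np.ndarray | None = None
    components: np.ndarray | None = None
    structure_matrix: sp.csr_matrix | None = None
    scaled: bool = False
    scale_factors: dict = field(default_factory=dict)

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    @property
    def n_components(self) -> int:
        if self.components is None:
            raise ValueError("adjacency not built")
        return int(self.components.max()) + 1

    def neighbour_sets(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_polygons)]
        for i, j in self.adjacency:
            out[i].add(j)
            out[j].add(i)
        return out

    def constraint_matrix(self) -> np.ndarray:
        """Per-component sum-to-zero constraint rows A (k_comp x n)."""
        k = self.n_components
        A = np.zeros((k, self.n_polygons))
        for c in range(k):
            A[c, self.components == c] = 1.0
        return A


def build_voronoi(
    towers: TowerSet,
    boundary: Polygon,
    *,
    jitter_seed: int = 0,
    build_graph: bool = True,
    scale: bool = True,
) -> PolygonSupport:
    """Tessellate the boundary into one clipped Voronoi cell per tower.

    Cells partition the boundary (relative area mismatch < 1e-6) and each
    tower lies in its own cell.  Degenerate seed configurations that the
    tessellation library rejects (e.g. exactly collinear points) are retried
    with a seeded jitter of ~1e-9 times the boundary diameter.

    With ``build_graph`` (default) the rook adjacency and the (optionally
    variance-scaled) structure matrix are derived immediately.
    """
    if boundary.area <= 0:
        raise ValueError("boundary must have positive area")
    pts = towers.points
    inside = shapely.contains_xy(boundary, pts[:, 0], pts[:, 1])
    if not inside.all():
        bad = np.flatnonzero(~inside).tolist()
        raise ValueError(f"towers outside boundary at indices {bad}")

    polygons = _clipped_cells(pts, boundary, jitter_seed)
    support = PolygonSupport(towers=towers, polygons=polygons, boundary=boundary)
    if build_graph:
        build_adjacency(support)
        build_structure_matrix(support, scale=scale)
    return support


def _clipped_cells(pts: np.ndarray, boundary: Polygon, jitter_seed: int) -> list:
    diam = max(boundary.bounds[2] - boundary.bounds[0], boundary.bounds[3] - boundary.bounds[1])
    envelope = shapely.box(*boundary.buffer(2.0 * diam).bounds)
    seed_pts = pts
    for attempt in range(3):
        try:
            raw = voronoi_diagram(MultiPoint(seed_pts.tolist()), envelope=envelope)
            cells = _match_cells(raw.geoms, seed_pts, boundary)
            return cells
        except (shapely.errors.GEOSException, ValueError) as err:  # degenerate seeds
            if attempt == 2:
                raise ValueError(f"tessellation failed after jitter retries: {err}") from err
            rng = np.random.default_rng(jitter_seed + attempt)
            seed_pts = pts + rng.normal(scale=1e-9 * diam, size=pts.shape)
            warnings.warn("degenerate tower configuration: applying seeded jitter")


def _match_cells(raw_cells, pts: np.ndarray, boundary: Polygon) -> list:
    """Order library cells by the seed point each one contains, then clip."""
    raw = list(raw_cells)
    tree = STRtree(raw)
    cells: list = [None] * len(pts)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for k in tree.query(p):
            if raw[k].covers(p):
                if cells[i] is not None:
                    raise ValueError(f"ambiguous cell for tower {i}")
                cells[i] = raw[k].intersection(boundary)
        if cells[i] is None or cells[i].is_empty:
            raise ValueError(f"no Voronoi cell found for tower {i}")
    total = sum(c.area for c in cells)
    if abs(total - boundary.area) > 1e-6 * boundary.area:
        raise ValueError("clipped cells do not partition the boundary")
    return cells


def build_adjacency(support: PolygonSupport, *, length_tol: float = 1e-12) -> PolygonSupport:
    """Fill rook adjacency: i ~ j iff cells share an edge of positive length.

    Corner-point contacts (zero-length intersections) do not count.  Isolated
    polygons are allowed; connected components are labelled by graph search.
    """
    polys = support.polygons
    n = len(polys)
    tree = STRtree(polys)
    edges: list[tuple[int, int]] = []
    for i in range(n):
        for j in tree.query(polys[i]):
            j = int(j)
            if j <= i:
                continue
            inter = polys[i].intersection(polys[j])
            if inter.length > length_tol:
                edges.append((i, j))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    comp = np.empty(n, dtype=int)
    for label, nodes in enumerate(sorted(nx.connected_components(g), key=min)):
        comp[list(nodes)] = label
    deg = np.zeros(n, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    support.adjacency = sorted(edges)
    support.n_neighbours = deg
    support.components = comp
    return support


def build_structure_matrix(support: PolygonSupport, *, scale: bool = True) -> PolygonSupport:
    """Fill the Besag structure matrix R = D - A, optionally variance-scaled.

    Scaling multiplies each connected component's block of R by the geometric
    mean of that component's constrained marginal variances (diagonal of the
    Moore-Penrose pseudo-inverse of the block), so that at tau = 1 the ICAR
    field has unit generalized variance.  Rows keep summing to zero.
    Singleton components cannot be scaled (no variance is defined); they are
    left unscaled with a warning.
    """
    if support.adjacency is None:
        build_adjacency(support)
    n = support.n_polygons
    rows, cols, vals = [], [], []
    for i, j in support.adjacency:
        rows += [i, j]
        cols += [j, i]
        vals += [-1.0, -1.0]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(support.n_neighbours.astype(float))
    R = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    support.scale_factors = {}
    if scale:
        R = R.tolil()
        for c in range(support.n_components):
            idx = np.flatnonzero(support.components == c)
            if len(idx) == 1:
                warnings.warn(f"component {c} is a singleton; left unscaled")
                support.scale_factors[c] = 1.0
                continue
            sub = R[np.ix_(idx, idx)].toarray()
            gv = np.exp(np.mean(np.log(constrained_marginal_variances(sub))))
            R[np.ix_(idx, idx)] = sub * gv
            support.scale_factors[c] = float(gv)
        R = R.tocsr()
    support.structure_matrix = R
    support.scaled = bool(scale)
    return support


def constrained_marginal_variances(R_block: np.ndarray) -> np.ndarray:
    """Marginal variances of a sum-to-zero ICAR field with structure ``R_block``.

    Equal to the diagonal of the Moore-Penrose pseudo-inverse of the
    (connected) block at tau = 1.
    """
    w, V = np.linalg.eigh(R_block)
    pos = w > w.max() * 1e-10
    if (~pos).sum() != 1:
        raise ValueError("block is not a single connected component")
    inv = (V[:, pos] / w[pos]) @ V[:, pos].T
    return np.diag(inv).copy()
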