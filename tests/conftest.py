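import numpy as np
import pytest
from shapely.geometry import box

from voromap.support import (
    PolygonSupport,
    TowerSet,
    build_adjacency,
    build_structure_matrix,
)


def make_grid_support(nrows: int, ncols: int, *, scale: bool = False,
                      extra_detached: int = 0) -> PolygonSupport:
    """Rectangular lattice of unit cells (plus optional detached cells far away).

    Gives a support with a known rook-adjacency graph without running the
    tessellation, for oracle tests of the graph/precision machinery.
    """
    polys, pts = [], []
    for r in range(nrows):
        for c in range(ncols):
            polys.append(box(c, r, c + 1, r + 1))
            pts.append((c + 0.5, r + 0.5))
    for k in range(extra_detached):
        polys.append(box(100 + 3 * k, 100, 101 + 3 * k, 101))
        pts.append((100.5 + 3 * k, 100.5))
    boundary = box(0, 0, ncols, nrows)  # nominal; not used by graph ops
    support = PolygonSupport(
        towers=TowerSet(points=np.array(pts)), polygons=polys, boundary=boundary
    )
    build_adjacency(support)
    build_structure_matrix(support, scale=scale)
    return support


def support_from_graph(n: int, edges: list[tuple[int, int]], *, scale: bool = False
                       ) -> PolygonSupport:
    """Support with an arbitrary prescribed graph (geometry-free)."""
    import networkx as nx

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
    pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    support = PolygonSupport(
        towers=TowerSet(points=pts),
        polygons=[box(i, 0, i + 1, 1) for i in range(n)],
        boundary=box(0, 0, n, 1),
    )
    support.adjacency = sorted((min(i, j), max(i, j)) for i, j in edges)
    support.n_neighbours = deg
    support.components = comp
    build_structure_matrix(support, scale=scale)
    return support


@pytest.fixture(scope="session")
def small_dataset():
    """One medium synthetic study reused across read-only tests."""
    from voromap.synthetic import SyntheticConfig, simulate_dataset

    return simulate_dataset(SyntheticConfig(n_towers_urban=20, n_towers_rural=40, seed=3))
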