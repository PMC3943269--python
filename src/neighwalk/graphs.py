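"""Neighborhood contiguity graphs and intrinsic-CAR field sampling.

The spatial half of the convolution (BYM) model needs a symmetric,
connected contiguity graph over neighborhoods. :class:`AdjacencyGraph`
wraps a :mod:`networkx` graph, adds the invariants the CAR prior needs
(symmetry, no self-loops, connectedness) and carries optional unit-square
polygons so posterior spatial effects can be exported as choropleths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .exceptions import InvalidArgumentError, IslandError

__all__ = ["AdjacencyGraph", "make_lattice", "sample_car_field"]


@dataclass
class AdjacencyGraph:
    """Symmetric neighborhood contiguity structure (binary weights).

    Parameters
    ----------
    node_ids : sequence
        Neighborhood identifiers, in a fixed canonical order. Effects
        vectors returned by the samplers follow this order.
    edges : sequence of pairs
        Unordered contiguity pairs of node ids.
    polygons : dict, optional
        node id -> list of (x, y) ring coordinates, for GeoJSON export.
    """

    node_ids: Sequence[Hashable]
    edges: Sequence[tuple]
    polygons: dict | None = None
    require_connected: bool = True
    _g: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for a, b in self.edges:
            if a == b:
                raise InvalidArgumentError(f"self-loop at node {a!r}")
            if not (g.has_node(a) and g.has_node(b)):
                raise InvalidArgumentError(f"edge ({a!r}, {b!r}) references unknown node")
            g.add_edge(a, b)
        if g.number_of_nodes() == 0:
            raise InvalidArgumentError("graph has no nodes")
        if self.require_connected and g.number_of_nodes() > 1 and not nx.is_connected(g):
            n_comp = nx.number_connected_components(g)
            raise IslandError(
                f"adjacency graph has {n_comp} components; the intrinsic CAR "
                "prior is undefined across islands (pass require_connected=False "
                "only if you know what you are doing)"
            )
        self._g = g
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def index_of(self, node_id) -> int:
        return self._index[node_id]

    def degrees(self) -> np.ndarray:
        return np.array([self._g.degree(n) for n in self.node_ids], dtype=float)

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as two integer index arrays (canonical node order)."""
        if self.n_edges == 0:
            return np.array([], dtype=int), np.array([], dtype=int)
        ii, jj = zip(*((self._index[a], self._index[b]) for a, b in self._g.edges()))
        return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W with binary contiguity weights."""
        return nx.laplacian_matrix(self._g, nodelist=list(self.node_ids)).toarray().astype(float)

    def coloring(self) -> list[np.ndarray]:
        """Partition node indices into independent sets (greedy coloring).

        Nodes within one color class are mutually non-adjacent, so their
        CAR full conditionals do not couple and can be Metropolis-updated
        simultaneously.
        """
        colors = nx.greedy_color(self._g, strategy="largest_first")
        n_colors = max(colors.values()) + 1
        out: list[list[int]] = [[] for _ in range(n_colors)]
        for nid, c in colors.items():
            out[c].append(self._index[nid])
        return [np.sort(np.asarray(c, dtype=int)) for c in out]

    def neighbor_lists(self) -> list[np.ndarray]:
        return [
            np.asarray([self._index[m] for m in self._g.neighbors(n)], dtype=int)
            for n in self.node_ids
        ]

    def khop_smoothing_matrix(self, k: int) -> np.ndarray:
        """Row-stochastic matrix averaging over the k-hop neighborhood
        (self included); used to generate spatially autocorrelated
        exposure fields."""
        if k < 0:
            raise InvalidArgumentError("k must be >= 0")
        J = self.n_nodes
        reach = np.eye(J, dtype=bool)
        adj = nx.to_numpy_array(self._g, nodelist=list(self.node_ids)) > 0
        hop = np.eye(J, dtype=bool)
        for _ in range(k):
            hop = hop @ adj | hop
            reach |= hop
        m = reach.astype(float)
        return m / m.sum(axis=1, keepdims=True)

    # -- persistence -----------------------------------------------------
    def to_edgelist(self, path) -> None:
        """Write a 2-column whitespace-delimited edge list."""
        with open(path, "w") as fh:
            for a, b in self._g.edges():
                fh.write(f"{a} {b}\n")

    @classmethod
    def from_edgelist(cls, path, node_ids: Iterable | None = None) -> "AdjacencyGraph":
        edges = []
        seen: dict = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 2:
                    raise InvalidArgumentError(f"malformed edge line: {line!r}")
                a, b = (_maybe_int(p) for p in parts)
                edges.append((a, b))
                seen.setdefault(a, None)
                seen.setdefault(b, None)
        ids = list(node_ids) if node_ids is not None else list(seen)
        return cls(node_ids=ids, edges=edges)

    def to_geojson(self, path, properties: dict | None = None) -> None:
        """Write polygons (if any) as a GeoJSON FeatureCollection.

        ``properties`` maps property name -> {node_id: value}.
        """
        if self.polygons is None:
            raise InvalidArgumentError("graph carries no polygons")
        properties = properties or {}
        feats = []
        for nid in self.node_ids:
            ring = [list(xy) for xy in self.polygons[nid]]
            if ring[0] != ring[-1]:
                ring = ring + [ring[0]]
            props = {"neighborhood_id": nid}
            for name, mapping in properties.items():
                props[name] = float(mapping[nid])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _maybe_int(token: str):
    try:
        return int(token)
    except ValueError:
        return token


def make_lattice(rows: int, cols: int, scheme: str = "rook") -> AdjacencyGraph:
    """Regular lattice of unit cells with rook or queen contiguity.

    A synthetic stand-in for a census-tract contiguity map: nodes are
    ``row * cols + col`` integers, polygons are the unit squares.

    Examples
    --------
    >>> g = make_lattice(3, 3)
    >>> g.n_nodes, g.n_edges
    (9, 12)
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("lattice dimensions must be >= 1")
    if rows * cols < 2:
        raise InvalidArgumentError("lattice must have at least 2 cells")
    if scheme not in ("rook", "queen"):
        raise InvalidArgumentError(f"unknown contiguity scheme {scheme!r}")

    def nid(r, c):
        return r * cols + c

    node_ids = [nid(r, c) for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((nid(r, c), nid(r, c + 1)))
            if r + 1 < rows:
                edges.append((nid(r, c), nid(r + 1, c)))
            if scheme == "queen":
                if r + 1 < rows and c + 1 < cols:
                    edges.append((nid(r, c), nid(r + 1, c + 1)))
                if r + 1 < rows and c - 1 >= 0:
                    edges.append((nid(r, c), nid(r + 1, c - 1)))
    polygons = {
        nid(r, c): [(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]
        for r in range(rows)
        for c in range(cols)
    }
    return AdjacencyGraph(node_ids=node_ids, edges=edges, polygons=polygons)


def sample_car_field(
    graph: AdjacencyGraph, tau: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw one intrinsic-CAR (ICAR) field under the sum-to-zero constraint.

    The intrinsic CAR with conditional SD ``tau`` and binary contiguity
    weights has improper joint density proportional to
    ``exp(-sum_(j~k) (v_j - v_k)^2 / (2 tau^2))``; restricted to the
    sum-to-zero subspace it is a proper Gaussian with covariance
    ``tau^2 * pinv(L)`` where ``L`` is the graph Laplacian. Sampling goes
    through the eigendecomposition of ``L`` (cheap at desk scale), using
    only the non-null eigenvectors, which enforces ``sum(v) == 0``
    exactly up to floating point.
    """
    if tau < 0:
        raise InvalidArgumentError("tau must be >= 0")
    if graph.n_nodes > 1 and not nx.is_connected(graph._g):
        raise IslandError("CAR field undefined on a disconnected graph")
    rng = np.random.default_rng(rng)
    J = graph.n_nodes
    if tau == 0 or J == 1:
        return np.zeros(J)
    lam, q = np.linalg.eigh(graph.laplacian())
    # one zero eigenvalue (constant vector) on a connected graph
    keep = lam > lam[-1] * 1e-10
    z = rng.standard_normal(keep.sum())
    v = q[:, keep] @ (z / np.sqrt(lam[keep]))
    v = tau * v
    return v - v.mean()
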