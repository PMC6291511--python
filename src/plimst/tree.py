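"""Minimum spanning tree backbone and its global / nodal metrics.

The weighted PLI network is converted to a distance graph (distance = 1/PLI,
so strong connections are short) and reduced to its minimum spanning tree with
Kruskal's algorithm: links are sorted by ascending distance and added one at a
time, discarding any that would close a loop, until all N nodes are connected
by M = N - 1 links.  The tree is treated as binary for all metrics; the source
PLI weights are retained only as provenance.

Global metrics: leaf fraction L/M, tree hierarchy Th = L / (2 M BC_max), and
degree divergence kappa = <k^2>/<k>.  Nodal metrics: degree, betweenness
centrality (normalized by (N-1)(N-2)/2, endpoints excluded) and eccentricity
(hop count to the farthest node).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix


@dataclass
class SpanningTree:
    """Loop-less connected subgraph with N nodes and N-1 edges."""

    n_nodes: int
    edges: list[tuple[int, int, float]]  # (i, j, source PLI weight), i < j
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs {self.n_nodes - 1} edges, "
                f"got {len(self.edges)}"
            )
        if not self.node_labels:
            self.node_labels = [f"ROI{i:02d}" for i in range(self.n_nodes)]
        self._adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _w in self.edges:
            self._adj[i].append(j)
            self._adj[j].append(i)

    @property
    def adjacency(self) -> list[list[int]]:
        return self._adj

    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def kruskal_mst(adj: ConnectivityMatrix) -> SpanningTree:
    """Minimum spanning tree on distances 1/PLI via Kruskal's algorithm.

    Ties are broken deterministically by (distance, smaller index, larger
    index).  Zero-PLI entries carry infinite distance and are never used: if
    the strictly-positive-PLI graph is disconnected the call fails, naming the
    components, rather than fabricating a meaningless backbone link.
    """
    v = adj.values
    n = adj.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    pos = w > 0
    with np.errstate(divide="ignore"):
        dist = np.where(pos, 1.0 / np.where(pos, w, 1.0), np.inf)
    order = sorted(range(len(w)), key=lambda k: (dist[k], int(iu[k]), int(ju[k])))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        if not pos[k]:
            break
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    if len(edges) < n - 1:
        comps: dict[int, list[str]] = {}
        for node in range(n):
            comps.setdefault(uf.find(node), []).append(adj.roi_labels[node])
        raise ValueError(
            f"positive-PLI graph is disconnected into {len(comps)} components: "
            f"{sorted(comps.values())}"
        )
    return SpanningTree(n, edges, list(adj.roi_labels))


def degree(tree: SpanningTree) -> np.ndarray:
    """Number of tree links incident on each node (integer >= 1)."""
    return np.array([len(a) for a in tree.adjacency], dtype=int)


def betweenness_centrality(tree: SpanningTree) -> np.ndarray:
    """Fraction of node pairs whose unique tree path passes through each node.

    Computed in O(N) from rooted subtree sizes: removing node v splits the
    tree into branches of sizes c_1..c_d (plus the rest); pairs routed through
    v are those with endpoints in different components.  Normalization is
    (N-1)(N-2)/2 with endpoints excluded; for N < 3 all values are 0.
    """
    n = tree.n_nodes
    bc = np.zeros(n)
    if n < 3:
        return bc
    # iterative post-order from node 0 to get subtree sizes
    parent = [-1] * n
    order: list[int] = []
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for w in tree.adjacency[u]:
            if not seen[w]:
                seen[w] = True
                parent[w] = u
                stack.append(w)
    size = [1] * n
    for u in reversed(order):
        if parent[u] >= 0:
            size[parent[u]] += size[u]
    for v in range(n):
        comp_sizes = []
        for w in tree.adjacency[v]:
            comp_sizes.append(size[w] if parent[w] == v else n - size[v])
        rest = n - 1
        through = rest * (rest - 1) // 2  # all pairs among the others ...
        for c in comp_sizes:
            through -= c * (c - 1) // 2  # ... minus pairs inside one branch
        bc[v] = through
    return bc / ((n - 1) * (n - 2) / 2)


def eccentricity(tree: SpanningTree) -> np.ndarray:
    """Hop distance from each node to its farthest node (BFS per node)."""
    n = tree.n_nodes
    ecc = np.zeros(n, dtype=int)
    for s in range(n):
        dist = [-1] * n
        dist[s] = 0
        q = deque([s])
        far = 0
        while q:
            u = q.popleft()
            far = max(far, dist[u])
            for w in tree.adjacency[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    q.append(w)
        ecc[s] = far
    return ecc


def leaf_fraction(tree: SpanningTree, denominator: str = "links") -> float:
    """Fraction of leaves (degree-1 nodes): L/M by default, L/N optionally.

    The two conventions differ by the constant factor N/(N-1) and cannot
    change any group-comparison conclusion.
    """
    deg = degree(tree)
    leaves = int(np.sum(deg == 1))
    if denominator == "links":
        return leaves / (tree.n_nodes - 1)
    if denominator == "nodes":
        return leaves / tree.n_nodes
    raise ValueError(f"denominator must be 'links' or 'nodes', got {denominator!r}")


def tree_hierarchy(tree: SpanningTree) -> float:
    """Th = L / (2 M BC_max): hub overload vs. communication efficiency."""
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy undefined for N < 3 (BC_max = 0)")
    deg = degree(tree)
    leaves = int(np.sum(deg == 1))
    m = tree.n_nodes - 1
    bc_max = float(betweenness_centrality(tree).max())
    return leaves / (2 * m * bc_max)


def degree_divergence(tree: SpanningTree) -> float:
    """kappa = <k^2> / <k> of the tree's degree sequence (>= 1)."""
    deg = degree(tree).astype(float)
    return float(np.mean(deg**2) / np.mean(deg))


def mst_membership(tree: SpanningTree) -> np.ndarray:
    """Binary indicator over all N(N-1)/2 unordered pairs (upper-triangular
    order); exactly N-1 entries are 1."""
    n = tree.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    es = tree.edge_set()
    return np.array([(int(i), int(j)) in es for i, j in zip(iu, ju)], dtype=int)


def global_metrics(tree: SpanningTree, leaf_denominator: str = "links") -> dict[str, float]:
    """The three global MST metrics as a name->value dict."""
    return {
        "leaf_fraction": leaf_fraction(tree, leaf_denominator),
        "tree_hierarchy": tree_hierarchy(tree),
        "degree_divergence": degree_divergence(tree),
    }


def nodal_metrics(tree: SpanningTree) -> dict[str, np.ndarray]:
    """The three nodal MST metrics as a name->per-node-array dict."""
    return {
        "degree": degree(tree).astype(float),
        "betweenness_centrality": betweenness_centrality(tree),
        "eccentricity": eccentricity(tree).astype(float),
    }
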