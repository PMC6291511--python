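import numpy as np
import pytest

from plimst import ConnectivityMatrix, SpanningTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(n: int, rng: np.random.Generator) -> SpanningTree:
    """Uniform random labelled tree via a random Prüfer sequence."""
    if n == 2:
        return SpanningTree(2, [(0, 1, 1.0)])
    prufer = rng.integers(0, n, size=n - 2)
    return tree_from_prufer(prufer, n)


def tree_from_prufer(prufer, n: int) -> SpanningTree:
    prufer = list(prufer)
    degree = [1] * n
    for x in prufer:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, x), max(leaf, x), 1.0))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(u, v), max(u, v), 1.0))
    return SpanningTree(n, edges)


def star_tree(n: int) -> SpanningTree:
    return SpanningTree(n, [(0, k, 1.0) for k in range(1, n)])


def path_tree(n: int) -> SpanningTree:
    return SpanningTree(n, [(k, k + 1, 1.0) for k in range(n - 1)])


def random_pli_matrix(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    """Random symmetric zero-diagonal matrix with distinct positive weights."""
    iu, ju = np.triu_indices(n, k=1)
    w = rng.permutation(len(iu)) + 1.0  # distinct
    w = w / (w.max() + 1)
    m = np.zeros((n, n))
    m[iu, ju] = w
    m += m.T
    return ConnectivityMatrix(m)
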