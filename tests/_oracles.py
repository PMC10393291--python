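"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the rule statements with naive
data structures (dicts, lists, linear scans) and without reusing the
package's mesh/graph machinery, so agreement with the fast implementations
is meaningful.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# mesh helpers (independent of gradparc.mesh)
# ---------------------------------------------------------------------------

def adjacency_from_triangles(n_vertices: int, triangles) -> list[set[int]]:
    neigh = [set() for _ in range(n_vertices)]
    for a, b, c in triangles:
        neigh[a].update((b, c))
        neigh[b].update((a, c))
        neigh[c].update((a, b))
    return neigh


def bfs_ring(neigh, v: int, k: int) -> set[int]:
    ring = {v}
    frontier = {v}
    for _ in range(k):
        nxt = set()
        for w in frontier:
            nxt |= neigh[w]
        nxt -= ring
        ring |= nxt
        frontier = nxt
    return ring


# ---------------------------------------------------------------------------
# watershed oracle
# ---------------------------------------------------------------------------

def oracle_watershed(n_vertices, triangles, values, defined):
    """Priority-flood watershed by linear scan.

    Seeding: a maximal edge-connected equal-value plateau among defined
    vertices seeds iff its 3-ring contains no strictly lower defined value;
    its lowest-index member carries the seed label.  Flooding: repeatedly
    take the (value, index)-smallest unlabeled defined vertex adjacent to at
    least one labeled vertex; it becomes boundary if its 1-ring touches two
    or more distinct regions, else it joins the single adjacent region.
    Returns (labels, boundary) with labels 0 on boundary/undefined vertices.
    """
    neigh = adjacency_from_triangles(n_vertices, triangles)
    values = np.asarray(values, dtype=float)
    defined = np.asarray(defined, dtype=bool)

    # plateaus
    visited = [False] * n_vertices
    labels = np.zeros(n_vertices, dtype=int)
    next_label = 1
    order = sorted(range(n_vertices))
    for v in order:
        if not defined[v] or visited[v]:
            continue
        comp = [v]
        visited[v] = True
        stack = [v]
        while stack:
            w = stack.pop()
            for u in neigh[w]:
                if defined[u] and not visited[u] and values[u] == values[v]:
                    visited[u] = True
                    comp.append(u)
                    stack.append(u)
        ring = set()
        for w in comp:
            ring |= bfs_ring(neigh, w, 3)
        ring -= set(comp)
        if any(defined[u] and values[u] < values[v] for u in ring):
            continue
        labels[min(comp)] = next_label
        next_label += 1

    boundary = np.zeros(n_vertices, dtype=bool)
    while True:
        frontier = [
            v
            for v in range(n_vertices)
            if defined[v]
            and labels[v] == 0
            and not boundary[v]
            and any(labels[u] > 0 for u in neigh[v])
        ]
        if not frontier:
            break
        v = min(frontier, key=lambda w: (values[w], w))
        adjacent = {labels[u] for u in neigh[v] if labels[u] > 0}
        if len(adjacent) >= 2:
            boundary[v] = True
        else:
            labels[v] = adjacent.pop()
    return labels, boundary


# ---------------------------------------------------------------------------
# graph efficiency oracle
# ---------------------------------------------------------------------------

def oracle_binarize_top(weights: np.ndarray, frac: float) -> np.ndarray:
    n = weights.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if math.isfinite(weights[i, j]):
                pairs.append((i, j, weights[i, j]))
    pairs.sort(key=lambda t: (-t[2], (t[0], t[1])))
    m = math.ceil(frac * len(pairs))
    out = np.zeros((n, n))
    for i, j, _ in pairs[:m]:
        out[i, j] = out[j, i] = 1.0
    return out


def oracle_node_local_efficiency(weights: np.ndarray, node: int, frac: float) -> float:
    binary = oracle_binarize_top(weights, frac)
    g = nx.from_numpy_array(binary)
    nbrs = [u for u in g.neighbors(node)]
    n = len(nbrs)
    if n < 2:
        return 0.0
    sub = g.subgraph(nbrs)
    total = 0.0
    for j in nbrs:
        lengths = nx.single_source_shortest_path_length(sub, j)
        for k in nbrs:
            if k != j and k in lengths:
                total += 1.0 / lengths[k]
    return total / (n * (n - 1))


def oracle_hausdorff(points_a: np.ndarray, points_b: np.ndarray, radius: float) -> float:
    def gc(p, q):
        return radius * math.acos(
            max(-1.0, min(1.0, float(np.dot(p, q)) / radius**2))
        )

    d_ab = max(min(gc(p, q) for q in points_b) for p in points_a)
    d_ba = max(min(gc(p, q) for q in points_a) for p in points_b)
    return max(d_ab, d_ba)
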