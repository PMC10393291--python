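"""Watershed-by-flooding kernel shared by boundary mapping and parcellation.

Seeding: local minima of the 3-ring neighborhood.  Ties are resolved at the
level of plateaus (maximal edge-connected sets of equal value): a plateau
seeds iff no strictly lower value exists in its 3-ring, and, among
equal-valued 3-ring outsiders, it holds the lowest vertex index.  A constant
map therefore produces one seed per connected component and no boundary.

Flooding: a single priority queue keyed by (value, vertex index) — global
ascending order, deterministic ties.  When a vertex is popped, the distinct
region labels among its already-labeled 1-ring neighbors decide its fate:
one label -> it joins that region and exposes its neighbors; two or more ->
it is an ambiguous location and becomes boundary (label 0, never propagates).

The inner loop is numba-compiled when numba is importable and falls back to
an identical pure-Python implementation otherwise.
"""

from __future__ import annotations

import heapq

import numpy as np


def _flood_python(indptr, indices, values, labels, boundary):
    """In-place flood. labels: >0 seeds, 0 unlabeled, -1 undefined."""
    heap: list[tuple[float, int]] = []
    V = len(values)
    in_heap = np.zeros(V, dtype=bool)
    for v in range(V):
        if labels[v] > 0:
            for u in indices[indptr[v]: indptr[v + 1]]:
                if labels[u] == 0 and not in_heap[u] and not boundary[u]:
                    heapq.heappush(heap, (values[u], u))
                    in_heap[u] = True
    while heap:
        _, v = heapq.heappop(heap)
        if labels[v] != 0 or boundary[v]:
            continue
        first = 0
        multiple = False
        for u in indices[indptr[v]: indptr[v + 1]]:
            lu = labels[u]
            if lu > 0:
                if first == 0:
                    first = lu
                elif lu != first:
                    multiple = True
                    break
        if multiple:
            boundary[v] = True
        elif first > 0:
            labels[v] = first
            for u in indices[indptr[v]: indptr[v + 1]]:
                if labels[u] == 0 and not in_heap[u] and not boundary[u]:
                    heapq.heappush(heap, (values[u], u))
                    in_heap[u] = True
    return labels, boundary


def _make_numba_flood():
    import numba

    @numba.njit(cache=False)
    def flood(indptr, indices, values, labels, boundary):  # pragma: no cover
        V = values.shape[0]
        cap = V + 1
        hv = np.empty(cap, dtype=np.float64)
        hi = np.empty(cap, dtype=np.int64)
        size = 0
        in_heap = np.zeros(V, dtype=np.bool_)

        def push(val, idx, size):
            i = size
            hv[i] = val
            hi[i] = idx
            size += 1
            while i > 0:
                p = (i - 1) // 2
                if hv[i] < hv[p] or (hv[i] == hv[p] and hi[i] < hi[p]):
                    hv[i], hv[p] = hv[p], hv[i]
                    hi[i], hi[p] = hi[p], hi[i]
                    i = p
                else:
                    break
            return size

        def pop(size):
            top = hi[0]
            size -= 1
            hv[0] = hv[size]
            hi[0] = hi[size]
            i = 0
            while True:
                l = 2 * i + 1
                r = l + 1
                m = i
                if l < size and (hv[l] < hv[m] or (hv[l] == hv[m] and hi[l] < hi[m])):
                    m = l
                if r < size and (hv[r] < hv[m] or (hv[r] == hv[m] and hi[r] < hi[m])):
                    m = r
                if m == i:
                    break
                hv[i], hv[m] = hv[m], hv[i]
                hi[i], hi[m] = hi[m], hi[i]
                i = m
            return top, size

        for v in range(V):
            if labels[v] > 0:
                for k in range(indptr[v], indptr[v + 1]):
                    u = indices[k]
                    if labels[u] == 0 and not in_heap[u] and not boundary[u]:
                        size = push(values[u], u, size)
                        in_heap[u] = True
        while size > 0:
            v, size = pop(size)
            if labels[v] != 0 or boundary[v]:
                continue
            first = 0
            multiple = False
            for k in range(indptr[v], indptr[v + 1]):
                lu = labels[indices[k]]
                if lu > 0:
                    if first == 0:
                        first = lu
                    elif lu != first:
                        multiple = True
                        break
            if multiple:
                boundary[v] = True
            elif first > 0:
                labels[v] = first
                for k in range(indptr[v], indptr[v + 1]):
                    u = indices[k]
                    if labels[u] == 0 and not in_heap[u] and not boundary[u]:
                        size = push(values[u], u, size)
                        in_heap[u] = True
        return labels, boundary

    return flood


try:
    _flood_fast = _make_numba_flood()
except Exception:  # numba unavailable or failed to compile
    _flood_fast = None


def flood_fill(indptr, indices, values, seed_labels):
    """Run the flood; returns (labels, boundary) without mutating inputs."""
    labels = np.asarray(seed_labels, dtype=np.int64).copy()
    boundary = np.zeros(len(values), dtype=bool)
    values = np.asarray(values, dtype=np.float64)
    if _flood_fast is not None:
        return _flood_fast(
            np.asarray(indptr, dtype=np.int64),
            np.asarray(indices, dtype=np.int64),
            values,
            labels,
            boundary,
        )
    return _flood_python(
        np.asarray(indptr), np.asarray(indices), values, labels, boundary
    )


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def ring3_table(mesh):
    """Padded (V, m) table of 3-ring neighbors (self excluded); pad == V."""
    ring = mesh.k_ring_matrix(3).tolil()
    V = mesh.n_vertices
    rows = [np.asarray([u for u in r if u != v]) for v, r in enumerate(ring.rows)]
    m = max((len(r) for r in rows), default=0)
    out = np.full((V, m), V, dtype=np.int64)
    for v, r in enumerate(rows):
        out[v, : len(r)] = r
    return out


def find_seeds(values, defined, ring3, neighbor_lists):
    """Seed labels (1..n) for the watershed; 0 elsewhere.

    ``values`` may contain NaN off ``defined``.  Returns an int64 array with
    -1 on undefined vertices.
    """
    V = len(values)
    vals = np.where(defined, values, np.inf)
    ext = np.append(vals, np.inf)  # sentinel for ring padding
    neigh_vals = ext[ring3]
    neigh_min = neigh_vals.min(axis=1) if ring3.size else np.full(V, np.inf)
    strict = defined & (vals < neigh_min)
    has_tie = defined & (vals == neigh_min) & np.isfinite(vals)
    seed_mask = strict.copy()
    if has_tie.any():
        seed_mask |= _plateau_seeds(vals, defined, ring3, neighbor_lists, has_tie)
    labels = np.zeros(V, dtype=np.int64)
    labels[~defined] = -1
    seeds = np.where(seed_mask)[0]
    labels[seeds] = np.arange(1, len(seeds) + 1)
    return labels


def _plateau_seeds(vals, defined, ring3, neighbor_lists, candidates):
    """Resolve tied candidate vertices via the plateau rule.

    A maximal edge-connected equal-value set (plateau) seeds iff its 3-ring
    contains no strictly lower value; the lowest-index member represents it.
    Equal values outside the plateau (not edge-connected to it) belong to a
    different basin and do not veto seeding, so a constant map still yields
    exactly one seed per connected component.
    """
    V = len(vals)
    seed = np.zeros(V, dtype=bool)
    visited = np.zeros(V, dtype=bool)
    for v in np.where(candidates)[0]:
        if visited[v]:
            continue
        # plateau component of v (1-ring connectivity, equal value)
        comp = [v]
        visited[v] = True
        stack = [v]
        val = vals[v]
        while stack:
            w = stack.pop()
            for u in neighbor_lists[w]:
                u = int(u)
                if defined[u] and not visited[u] and vals[u] == val:
                    visited[u] = True
                    comp.append(u)
                    stack.append(u)
        comp_set = set(comp)
        ok = True
        for w in comp:
            for u in ring3[w]:
                u = int(u)
                if u >= V or u in comp_set or not defined[u]:
                    continue
                if vals[u] < val:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            seed[min(comp)] = True
    return seed


def watershed(mesh, values, defined=None, ring3=None):
    """Full watershed of one scalar field on a mesh.

    Returns ``(labels, boundary)``: labels > 0 are region ids (dense from 1),
    0 marks boundary/unreached/undefined vertices, and ``boundary`` is the
    boolean ambiguous-location mask.
    """
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = np.isfinite(values) & mesh.cortex_mask
    if not defined.any():
        raise ValueError("watershed input is undefined everywhere")
    if ring3 is None:
        ring3 = ring3_table(mesh)
    seeds = find_seeds(values, defined, ring3, mesh.neighbor_lists)
    a = mesh.adjacency
    filled = np.where(defined, values, np.inf)
    labels, boundary = flood_fill(a.indptr, a.indices, filled, seeds)
    labels[labels < 0] = 0
    return labels, boundary
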