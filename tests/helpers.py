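"""Small builders shared by the test suite."""

import numpy as np

from gradparc.parcellation import Parcellation


def connected_parcellation(mesh, sizes, starts=None):
    """Parcellation whose parcels are BFS-grown connected patches.

    ``sizes`` are vertex counts; parcels are carved from previously
    unassigned vertices so they are disjoint and edge-connected.
    """
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    assigned = np.zeros(mesh.n_vertices, dtype=bool)
    assigned |= mesh.medial_wall
    for pid, size in enumerate(sizes, start=1):
        if starts is not None and pid - 1 < len(starts):
            start = starts[pid - 1]
        else:
            start = int(np.argmin(assigned))  # lowest unassigned vertex
        patch = [start]
        assigned[start] = True
        frontier = [start]
        while len(patch) < size and frontier:
            nxt = []
            for v in frontier:
                for u in mesh.neighbor_lists[v]:
                    u = int(u)
                    if not assigned[u] and len(patch) < size:
                        assigned[u] = True
                        patch.append(u)
                        nxt.append(u)
            frontier = nxt
        if len(patch) != size:
            raise RuntimeError("could not grow a connected patch of that size")
        labels[patch] = pid
    return Parcellation(labels, mesh)
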