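"""Spherical cortical surface meshes and per-vertex scalar maps.

The substrate for every computation in this package is a 2-manifold
triangle mesh with a spherical mapping: each vertex carries its anatomical
position (mm), its position on a sphere of fixed radius (mm, FreeSurfer-style
100 mm by default), and a medial-wall flag.  Vertices on the medial wall are
non-cortical and excluded from all functional statistics; scalar maps mark
them with NaN rather than zero so they can never silently enter an average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import sparse

DEFAULT_SPHERE_RADIUS = 100.0


def nanmean_quiet(arr, axis=None, keepdims=False):
    """np.nanmean without the all-NaN-slice RuntimeWarning (returns NaN)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(arr, axis=axis, keepdims=keepdims)


class MeshError(ValueError):
    """Raised for invalid meshes, vertex ids, or off-sphere coordinates."""


@dataclass(eq=False)
class TriangleMesh:
    """Triangulated cortical surface with a spherical mapping.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Anatomical vertex positions in mm.
    triangles : (F, 3) int array
        Vertex index triples; consistently oriented.
    sphere_coords : (V, 3) float array
        Per-vertex position on the sphere of radius ``radius``.
    medial_wall : (V,) bool array
        True for non-cortical vertices excluded from functional statistics.
    hemisphere : str
        'L' or 'R'.
    radius : float
        Sphere radius in mm.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    sphere_coords: np.ndarray
    medial_wall: np.ndarray
    hemisphere: str = "L"
    radius: float = DEFAULT_SPHERE_RADIUS

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        V = self.n_vertices
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= V
        ):
            raise MeshError("triangle indices out of range")
        if self.medial_wall.shape != (V,):
            raise MeshError("medial_wall length must equal vertex count")
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if np.any(np.abs(norms - self.radius) > 1e-6 * self.radius):
            raise MeshError("sphere coordinates are not on the sphere")
        if self.hemisphere not in ("L", "R"):
            raise MeshError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        # 2-manifold: each undirected edge in at most 2 triangles
        e = self._edge_array()
        if e.size:
            _, counts = np.unique(e, axis=0, return_counts=True)
            if np.any(counts > 2):
                raise MeshError("mesh is not 2-manifold (edge shared by >2 triangles)")

    def _edge_array(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    # -- derived structure ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @cached_property
    def cortex_mask(self) -> np.ndarray:
        """Boolean mask of non-medial-wall (cortical) vertices."""
        return ~self.medial_wall

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric V x V vertex adjacency (mesh edges)."""
        e = np.unique(self._edge_array(), axis=0)
        data = np.ones(len(e), dtype=np.int8)
        a = sparse.coo_matrix(
            (data, (e[:, 0], e[:, 1])), shape=(self.n_vertices,) * 2
        )
        a = a + a.T
        return a.tocsr()

    @cached_property
    def neighbor_lists(self) -> list[np.ndarray]:
        a = self.adjacency
        return [a.indices[a.indptr[i]: a.indptr[i + 1]] for i in range(self.n_vertices)]

    @cached_property
    def vertex_triangles(self) -> list[np.ndarray]:
        """Triangles incident to each vertex."""
        lists: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for t, (a, b, c) in enumerate(self.triangles):
            lists[a].append(t)
            lists[b].append(t)
            lists[c].append(t)
        return [np.asarray(l, dtype=np.int64) for l in lists]

    @cached_property
    def mean_edge_length(self) -> float:
        """Mean great-circle edge length on the sphere (mm)."""
        e = np.unique(self._edge_array(), axis=0)
        return float(
            np.mean(
                geodesic_sphere_distance(
                    self.sphere_coords[e[:, 0]],
                    self.sphere_coords[e[:, 1]],
                    self.radius,
                )
            )
        )

    def k_ring_matrix(self, k: int) -> sparse.csr_matrix:
        """Boolean V x V reachability within <= k edges (includes self)."""
        eye = sparse.identity(self.n_vertices, dtype=bool, format="csr")
        if k == 0:
            return eye
        a = self.adjacency.astype(bool) + eye
        out = eye
        for _ in range(k):
            out = (out @ a).astype(bool)
        return out.tocsr()


@dataclass(eq=False)
class ScalarMap:
    """One real value per mesh vertex; NaN marks undefined (medial wall).

    ``smoothing_sigma`` records the Gaussian kernel width (mm) applied on
    the surface, 0 for an unsmoothed map.
    """

    values: np.ndarray
    mesh: TriangleMesh
    smoothing_sigma: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.shape != (self.mesh.n_vertices,):
            raise MeshError("map length must equal vertex count of its mesh")
        self.values[self.mesh.medial_wall] = np.nan

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values) & self.mesh.cortex_mask

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def k_ring_neighborhood(mesh: TriangleMesh, vertex: int, k: int) -> set[int]:
    """Vertices reachable from ``vertex`` by at most ``k`` mesh edges.

    Includes ``vertex`` itself (the 0-ring).  Membership is symmetric:
    ``u in ring_k(v)`` iff ``v in ring_k(u)``.
    """
    if not 0 <= vertex < mesh.n_vertices:
        raise IndexError(f"vertex id {vertex} out of range [0, {mesh.n_vertices})")
    if k < 0:
        raise ValueError("k must be >= 0")
    ring = {vertex}
    frontier = [vertex]
    for _ in range(k):
        nxt = []
        for v in frontier:
            for u in mesh.neighbor_lists[v]:
                u = int(u)
                if u not in ring:
                    ring.add(u)
                    nxt.append(u)
        if not nxt:
            break
        frontier = nxt
    return ring


def geodesic_sphere_distance(a, b, radius: float = DEFAULT_SPHERE_RADIUS):
    """Great-circle distance (mm) between points on a sphere of ``radius``.

    Accepts single points or broadcastable (..., 3) arrays; symmetric and
    bounded by pi*radius.  Raises if an input is off the sphere by more than
    1e-6 relative tolerance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(np.abs(na - radius) > 1e-6 * radius) or np.any(
        np.abs(nb - radius) > 1e-6 * radius
    ):
        raise MeshError("input point(s) not on the sphere of the given radius")
    cosang = np.sum(a * b, axis=-1) / (na * nb)
    return radius * np.arccos(np.clip(cosang, -1.0, 1.0))


from functools import lru_cache


@lru_cache(maxsize=32)
def _gaussian_kernel_cached(mesh: TriangleMesh, sigma: float) -> sparse.csr_matrix:
    return _build_gaussian_kernel(mesh, sigma)


def _gaussian_kernel(mesh: TriangleMesh, sigma: float) -> sparse.csr_matrix:
    # meshes are immutable after construction; cache by identity
    return _gaussian_kernel_cached(mesh, float(sigma))


def _build_gaussian_kernel(mesh: TriangleMesh, sigma: float) -> sparse.csr_matrix:
    """Doubly stochastic spherical Gaussian kernel over cortical vertices.

    Weights exp(-d^2 / 2 sigma^2) with great-circle distances, truncated at
    3 sigma via a k-ring cutoff, then Sinkhorn-balanced so that both constants
    and the map mean are preserved exactly.  Medial-wall rows/columns are
    identity so no weight ever crosses the wall.
    """
    cutoff = 3.0 * sigma
    k = max(1, int(np.ceil(cutoff / max(mesh.mean_edge_length, 1e-12))))
    ring = mesh.k_ring_matrix(k).tocoo()
    i, j = ring.row, ring.col
    cortex = mesh.cortex_mask
    keep = cortex[i] & cortex[j]
    i, j = i[keep], j[keep]
    d = geodesic_sphere_distance(
        mesh.sphere_coords[i], mesh.sphere_coords[j], mesh.radius
    )
    keep = d <= cutoff
    i, j, d = i[keep], j[keep], d[keep]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    V = mesh.n_vertices
    W = sparse.coo_matrix((w, (i, j)), shape=(V, V)).tocsr()
    # identity on the medial wall
    wall = np.where(~cortex)[0]
    if wall.size:
        W = W + sparse.coo_matrix(
            (np.ones(wall.size), (wall, wall)), shape=(V, V)
        )
    # symmetric Sinkhorn: find x > 0 with diag(x) W diag(x) doubly stochastic;
    # W is symmetric with positive diagonal so this converges quickly
    x = np.ones(V)
    for _ in range(500):
        rs = x * (W @ x)
        if np.max(np.abs(rs - 1.0)) < 1e-13:
            break
        x /= np.sqrt(rs)
    return (sparse.diags(x) @ W @ sparse.diags(x)).tocsr()


def smooth_scalar_map(smap: ScalarMap, mesh: TriangleMesh, sigma: float) -> ScalarMap:
    """Geodesic-Gaussian smoothing of a scalar map on the sphere.

    sigma is the kernel width in mm (the cortical default used throughout
    this package is 2.55 mm).  sigma == 0 returns the map unchanged.
    Constant maps are fixed points and the cortical mean is preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ScalarMap(smap.values.copy(), mesh, smoothing_sigma=0.0, name=smap.name)
    K = _gaussian_kernel(mesh, sigma)
    vals = smap.values.copy()
    bad = ~np.isfinite(vals)
    filled = np.where(bad, 0.0, vals)
    out = K @ filled
    if bad.any():
        # renormalize rows that lost weight to undefined vertices
        mass = K @ (~bad).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out / mass
        out[bad] = np.nan
    return ScalarMap(out, mesh, smoothing_sigma=sigma, name=smap.name)


def smooth_vertex_field(mesh: TriangleMesh, field: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth a (V, d) vector field componentwise with the spherical kernel."""
    if sigma <= 0:
        return field.copy()
    K = _gaussian_kernel(mesh, sigma)
    return np.asarray(K @ field)
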