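"""Local gradients of functional connectivity and boundary mapping.

From a second-order connectivity matrix, each row (the RSFC-2nd profile of a
seed vertex) is differentiated on the surface — a per-triangle linear
gradient whose magnitude is area-averaged to vertices — giving a V x V
gradient matrix.  Watershed boundary detection on every row yields V binary
boundary maps whose vertex-wise average is the *local gradient map*: values
in [0, 1], high where functional connectivity transitions abruptly, i.e. at
putative areal borders.

Scan-level maps are then combined hierarchically (phase-encoding pairs ->
session -> visit -> age group -> age independent) by unweighted means so
each unit at the grouped level contributes equally; no smoothing is applied
at any combination step.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse

from ._watershed import ring3_table, watershed
from .mesh import ScalarMap, TriangleMesh, nanmean_quiet

_DEGENERATE_AREA = 1e-12


class DegenerateTriangleError(ValueError):
    pass


@dataclass(eq=False)
class LocalGradientMap(ScalarMap):
    """Average of binary watershed boundary maps; values in [0, 1].

    ``group_label`` records the aggregation level: scan, session, visit,
    age group label, or 'age-independent'.
    """

    n_boundary_maps: int = 0
    group_label: str = "scan"


@dataclass(eq=False)
class GradientMatrix:
    """V x V matrix whose row v is the gradient-magnitude map of the
    RSFC-2nd profile seeded at v.  Undefined rows are NaN."""

    matrix: np.ndarray
    mesh: TriangleMesh

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.mesh.n_vertices,) * 2:
            raise ValueError("gradient matrix must be V x V on its mesh")
        if np.nanmin(m) < -1e-12:
            raise ValueError("gradient magnitudes must be nonnegative")
        self.matrix = m


class GradientOperator:
    """Per-mesh cached machinery for surface gradients and watersheds."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self._build()

    def _build(self) -> None:
        mesh = self.mesh
        p = mesh.sphere_coords
        tri = mesh.triangles
        e1 = p[tri[:, 1]] - p[tri[:, 0]]
        e2 = p[tri[:, 2]] - p[tri[:, 0]]
        n = np.cross(e1, e2)
        area2 = np.linalg.norm(n, axis=1)  # 2 * triangle area
        bad = np.where(area2 < _DEGENERATE_AREA)[0]
        if bad.size:
            raise DegenerateTriangleError(
                f"zero-area triangle(s) {bad.tolist()} in mesh"
            )
        # orthonormal basis (u, w) of each triangle plane
        u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        w = np.cross(n / area2[:, None], u)
        # solve [[e1.u, e1.w], [e2.u, e2.w]] g = [f1-f0, f2-f0]
        a = np.einsum("ij,ij->i", e1, u)
        b = np.einsum("ij,ij->i", e1, w)
        c = np.einsum("ij,ij->i", e2, u)
        d = np.einsum("ij,ij->i", e2, w)
        det = a * d - b * c
        # grad_u = (d*(f1-f0) - b*(f2-f0))/det ; grad_w = (-c*(f1-f0) + a*(f2-f0))/det
        self._gu = np.stack([-(d - b), d, -b], axis=1) / det[:, None]
        self._gw = np.stack([-(a - c), -c, a], axis=1) / det[:, None]
        self._basis_u = u
        self._basis_w = w
        self._tri = tri
        # vertex aggregation: area-weighted mean over incident triangles,
        # excluding triangles that touch the medial wall
        wall = mesh.medial_wall
        tri_ok = ~wall[tri].any(axis=1)
        areas = 0.5 * area2
        rows, cols, vals = [], [], []
        for corner in range(3):
            rows.append(tri[:, corner][tri_ok])
            cols.append(np.where(tri_ok)[0])
            vals.append(areas[tri_ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        V, F = mesh.n_vertices, mesh.n_triangles
        agg = sparse.coo_matrix((vals, (rows, cols)), shape=(V, F)).tocsr()
        rowsum = np.asarray(agg.sum(axis=1)).ravel()
        self._no_triangle = rowsum == 0
        rowsum[rowsum == 0] = 1.0
        self.aggregate = sparse.diags(1.0 / rowsum) @ agg
        self.ring3 = ring3_table(mesh)

    def magnitudes(self, maps: np.ndarray) -> np.ndarray:
        """Vertex gradient magnitudes for a batch of maps (n, V) -> (n, V)."""
        maps = np.atleast_2d(np.asarray(maps, dtype=float))
        tri = self._tri
        f = maps[:, tri]  # (n, F, 3)
        gu = np.einsum("nfc,fc->nf", f, self._gu)
        gw = np.einsum("nfc,fc->nf", f, self._gw)
        mag = np.hypot(gu, gw)
        out = (self.aggregate @ mag.T).T
        out[:, self._no_triangle] = np.nan
        out[:, self.mesh.medial_wall] = np.nan
        return out

    def vectors(self, values: np.ndarray) -> np.ndarray:
        """3-D tangent gradient vectors of one map, area-averaged to vertices.

        Undefined (NaN) inputs are treated as 0; the per-vertex vector is
        projected onto the sphere tangent plane.  Returns (V, 3).
        """
        f = np.where(np.isfinite(values), values, 0.0)[self._tri]  # (F, 3)
        gu = np.einsum("fc,fc->f", f, self._gu)
        gw = np.einsum("fc,fc->f", f, self._gw)
        vec = gu[:, None] * self._basis_u + gw[:, None] * self._basis_w  # (F, 3)
        out = self.aggregate @ vec
        # project to tangent plane at each vertex
        p = self.mesh.sphere_coords / self.mesh.radius
        out = out - p * np.einsum("ij,ij->i", out, p)[:, None]
        out[self._no_triangle] = 0.0
        return out


@lru_cache(maxsize=8)
def _operator_cache(mesh_key):
    mesh = mesh_key[0]
    return GradientOperator(mesh)


def get_operator(mesh: TriangleMesh) -> GradientOperator:
    # id-keyed cache; meshes are treated as immutable after construction
    return _operator_cache((mesh,))


def spatial_gradient(smap: ScalarMap, mesh: TriangleMesh) -> ScalarMap:
    """Gradient-magnitude map of a scalar field on the surface.

    Per-triangle linear gradients in the triangle (tangent) plane, magnitude
    area-averaged to vertices; triangles touching the medial wall are
    excluded.  Nonnegative everywhere defined; invariant to adding a
    constant to the field.
    """
    op = get_operator(mesh)
    vals = op.magnitudes(smap.values[None, :])[0]
    return ScalarMap(vals, mesh, name=f"grad({smap.name})")


def gradient_matrix(rsfc2, mesh: TriangleMesh) -> GradientMatrix:
    """Apply the surface gradient to every row of an RSFC-2nd matrix."""
    m = rsfc2.matrix if hasattr(rsfc2, "matrix") else np.asarray(rsfc2, float)
    op = get_operator(mesh)
    undef_rows = ~np.isfinite(m).any(axis=1)
    filled = np.where(np.isfinite(m), m, 0.0)
    out = op.magnitudes(filled)
    out[undef_rows] = np.nan
    return GradientMatrix(out, mesh)


def watershed_boundary_map(gradient_row, mesh: TriangleMesh, ring3=None) -> ScalarMap:
    """Binary boundary map of one gradient row via watershed flooding.

    Seeds are 3-ring local minima; regions grow in ascending gradient order;
    vertices reachable from two or more regions at their flooding step are
    ambiguous locations and marked 1, all others 0.
    """
    values = gradient_row.values if isinstance(gradient_row, ScalarMap) else np.asarray(
        gradient_row, dtype=float
    )
    defined = np.isfinite(values) & mesh.cortex_mask
    if not defined.any():
        raise ValueError("gradient row is undefined everywhere")
    if np.nanmin(values[defined]) < -1e-12:
        raise ValueError("gradient row must be nonnegative")
    _, boundary = watershed(mesh, values, defined=defined, ring3=ring3)
    out = boundary.astype(float)
    out[~defined] = np.nan
    return ScalarMap(out, mesh, name="boundary")


def local_gradient_map(
    boundary_maps, mesh: TriangleMesh | None = None, group_label: str = "scan"
) -> LocalGradientMap:
    """Vertex-wise mean of binary boundary maps -> local gradient map."""
    maps = list(boundary_maps)
    if not maps:
        raise ValueError("no boundary maps to average")
    if mesh is None:
        mesh = maps[0].mesh
    arr = np.stack(
        [m.values if isinstance(m, ScalarMap) else np.asarray(m, float) for m in maps]
    )
    finite = np.isfinite(arr)
    if not np.all((arr[finite] == 0) | (arr[finite] == 1)):
        raise ValueError("boundary maps must be binary")
    mean = np.where(finite.any(axis=0), nanmean_quiet(arr, axis=0), np.nan)
    return LocalGradientMap(
        mean, mesh, n_boundary_maps=len(maps), group_label=group_label
    )


def boundary_maps_from_gradient_matrix(gmat: GradientMatrix) -> np.ndarray:
    """All per-seed binary boundary maps of a gradient matrix, (V, V)."""
    mesh = gmat.mesh
    op = get_operator(mesh)
    out = np.full_like(gmat.matrix, np.nan)
    for i, row in enumerate(gmat.matrix):
        if not np.isfinite(row).any():
            continue
        out[i] = watershed_boundary_map(row, mesh, ring3=op.ring3).values
    return out


def scan_local_gradient_map(gmat: GradientMatrix) -> LocalGradientMap:
    """Local gradient map of one scan: average of its V boundary maps."""
    bmaps = boundary_maps_from_gradient_matrix(gmat)
    valid = np.isfinite(bmaps).any(axis=1)
    return local_gradient_map(list(bmaps[valid]), gmat.mesh, group_label="scan")


def combine_maps(maps, group_keys, group_label: str = "group"):
    """Average local gradient maps within groups, unweighted, unsmoothed.

    ``group_keys`` is one key per map (e.g. session ids when collapsing
    AP/PA phase-encoding pairs).  Returns ``{key: LocalGradientMap}``;
    applying this repeatedly up the hierarchy (scan -> session -> visit ->
    age group -> age independent) keeps each unit at the grouped level
    contributing equally.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to combine")
    if len(group_keys) != len(maps):
        raise ValueError("one group key required per map (missing metadata?)")
    if any(k is None for k in group_keys):
        raise ValueError("grouping key missing in metadata")
    out = {}
    for key in dict.fromkeys(group_keys):  # preserve first-seen order
        members = [m for m, k in zip(maps, group_keys) if k == key]
        arr = np.stack([m.values for m in members])
        mean = nanmean_quiet(arr, axis=0)
        mean[~np.isfinite(arr).any(axis=0)] = np.nan
        out[key] = LocalGradientMap(
            mean,
            members[0].mesh,
            n_boundary_maps=int(np.sum([m.n_boundary_maps for m in members])),
            group_label=f"{group_label}:{key}",
        )
    return out


def age_independent_map(age_maps) -> LocalGradientMap:
    """Unweighted mean of the age-related maps (each age counts equally)."""
    combined = combine_maps(
        list(age_maps), ["all"] * len(list(age_maps)), group_label="age-independent"
    )
    out = combined["all"]
    out.group_label = "age-independent"
    return out


def binarize_top(smap: ScalarMap, frac: float) -> ScalarMap:
    """Binarize a map to its top fraction of defined values.

    Exactly ``ceil(frac * N_defined)`` vertices are set to 1; ties at the
    cutoff are broken by vertex index (lower index wins).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    defined = smap.defined
    idx = np.where(defined)[0]
    vals = smap.values[idx]
    m = int(np.ceil(frac * len(idx)))
    order = np.lexsort((idx, -vals))  # by value desc, then vertex index asc
    top = idx[order[:m]]
    out = np.full(smap.mesh.n_vertices, np.nan)
    out[idx] = 0.0
    out[top] = 1.0
    return ScalarMap(out, smap.mesh, name=f"top{frac:g}({smap.name})")


def overlap_consistency(maps, top_frac: float) -> ScalarMap:
    """Sum of per-map top-fraction binarizations (age-consistency map).

    With six age-related maps the output counts, per vertex, in how many age
    groups (0..6) the vertex ranks in the top fraction of local gradient.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    total = None
    for m in maps:
        b = binarize_top(m, top_frac).values
        total = b if total is None else np.where(
            np.isfinite(b) & np.isfinite(total), total + b, np.nan
        )
    return ScalarMap(total, maps[0].mesh, name=f"consistency_top{top_frac:g}")
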