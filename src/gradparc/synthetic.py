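"""Synthetic spherical cortex cohorts for end-to-end pipeline testing.

Emulates the structure of a longitudinal infant rs-fMRI cohort with no data
download: an icosphere stands in for the spherical cortical surface (with a
polar cap playing the medial wall), a geodesic Voronoi tessellation is the
ground-truth areal parcellation, parcels share network-level latent signals
(yielding planted functional networks), and each subject's functional layout
is displaced by a smooth random spherical warp to emulate inter-individual
misalignment.  All generators are pure functions of their spec and seed.

Signal model per vertex v with parcel p(v) and network g(p):

    x_v(t) = snr * [ sqrt(c) * s_p(t) + sqrt(1-c) * z_v(t) ] + e_v(t)
    s_p(t) = sqrt(w) * h_g(t) + sqrt(1-w) * u_p(t)

with h, u, z unit-variance AR(1) latents (rho = 0.3, so correlation
estimates have realistic variance rather than white-noise optimism) and e
i.i.d. standard normal vertex noise; ``snr`` is the parcel-signal to
vertex-noise standard-deviation ratio, ``c`` the within-parcel coherence and
``w`` the within-network coupling between parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .connectivity import ScanTimeSeries
from .mesh import (
    DEFAULT_SPHERE_RADIUS,
    TriangleMesh,
    geodesic_sphere_distance,
    smooth_vertex_field,
)
from .parcellation import Parcellation

DAYS_PER_MONTH = 365.25 / 12.0
DEFAULT_AGE_GROUPS_MONTHS = (3, 6, 9, 12, 18, 24)


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

def icosphere(
    subdivisions: int,
    radius: float = DEFAULT_SPHERE_RADIUS,
    hemisphere: str = "L",
    medial_cap_frac: float = 0.0,
) -> TriangleMesh:
    """Recursively subdivided icosahedron projected to a sphere.

    Vertex count is 10 * 4**s + 2; faces are consistently outward-oriented.
    ``medial_cap_frac`` marks that fraction of vertices (those nearest the
    north pole) as medial wall.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    # consistent outward orientation
    cent = verts[faces].mean(axis=1)
    n = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]])
    flip = np.einsum("ij,ij->i", cent, n) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    coords = verts * radius
    V = len(coords)
    wall = np.zeros(V, dtype=bool)
    if medial_cap_frac > 0:
        n_wall = int(np.ceil(medial_cap_frac * V))
        wall[np.argsort(-coords[:, 2])[:n_wall]] = True
    return TriangleMesh(
        coords.copy(), faces, coords.copy(), wall, hemisphere=hemisphere, radius=radius
    )


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    cache: dict[tuple[int, int], int] = {}
    new_verts = [v for v in verts]

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = new_verts[a] + new_verts[b]
            m /= np.linalg.norm(m)
            cache[key] = len(new_verts)
            new_verts.append(m)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.asarray(new_verts), np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _edge_weighted_graph(mesh: TriangleMesh) -> csr_matrix:
    a = mesh.adjacency.tocoo()
    w = geodesic_sphere_distance(
        mesh.sphere_coords[a.row], mesh.sphere_coords[a.col], mesh.radius
    )
    return csr_matrix((w, (a.row, a.col)), shape=a.shape)


def synth_parcellation(
    mesh: TriangleMesh, n_parcels: int, rng: np.random.Generator
) -> Parcellation:
    """Geodesic Voronoi ground-truth parcellation from random seed vertices.

    All parcels are edge-connected and nonempty; medial wall stays 0.
    """
    cortex = np.where(mesh.cortex_mask)[0]
    if n_parcels > cortex.size:
        raise ValueError("more parcels requested than cortical vertices")
    graph = _edge_weighted_graph(mesh)
    # cut the medial wall out of the graph so parcels cannot tunnel through
    from scipy.sparse import diags

    keep = diags(mesh.cortex_mask.astype(float))
    graph = (keep @ graph @ keep).tocsr()
    # farthest-point sampling from a random start: cortical areas are
    # roughly evenly sized, so seeds are spread rather than Poisson-random
    seeds = [int(rng.choice(cortex))]
    mind = dijkstra(graph, indices=seeds[0], directed=False, min_only=True)
    for _ in range(1, n_parcels):
        cand = cortex[np.argmax(mind[cortex])]
        seeds.append(int(cand))
        d = dijkstra(graph, indices=cand, directed=False, min_only=True)
        mind = np.minimum(mind, d)
    seeds = np.asarray(seeds)
    dist = dijkstra(graph, indices=seeds, directed=False)
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[cortex] = np.argmin(dist[:, cortex], axis=0) + 1
    return Parcellation(labels, mesh, provenance="synthetic-voronoi")


def synth_network_labels(
    n_parcels: int, n_networks: int, rng: np.random.Generator
) -> np.ndarray:
    """Balanced random parcel -> network assignment (sizes differ by <= 1).

    Equal-sized planted networks keep the network-count recovery problem
    well posed: with unequal sizes a coarser merge of networks can become
    systematically optimal and spuriously stable.
    """
    if n_networks > n_parcels:
        raise ValueError("more networks than parcels")
    labels = np.resize(np.arange(1, n_networks + 1), n_parcels)
    rng.shuffle(labels)
    return labels


def random_smooth_warp(
    mesh: TriangleMesh, max_angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random spherical displacement field (V, 3) of target positions.

    A band-limited tangent field (white noise smoothed with a wide spherical
    Gaussian) scaled so the largest angular displacement equals
    ``max_angle_deg``.
    """
    if max_angle_deg <= 0:
        return mesh.sphere_coords.copy()
    field = rng.standard_normal((mesh.n_vertices, 3))
    field = smooth_vertex_field(mesh, field, sigma=0.35 * mesh.radius)
    p = mesh.sphere_coords / mesh.radius
    field -= p * np.einsum("ij,ij->i", field, p)[:, None]
    ang = np.linalg.norm(field, axis=1)
    scale = np.deg2rad(max_angle_deg) * mesh.radius / max(ang.max(), 1e-12)
    pos = mesh.sphere_coords + scale * field
    pos *= mesh.radius / np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def _ar1(rng: np.random.Generator, shape, rho: float = 0.3) -> np.ndarray:
    """Unit-variance stationary AR(1) series along the last axis."""
    n = shape[-1]
    x = np.empty(shape)
    e = rng.standard_normal(shape)
    x[..., 0] = e[..., 0]
    c = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        x[..., t] = rho * x[..., t - 1] + c * e[..., t]
    return x


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    battery: an s=3 icosphere (642 vertices), 20 planted parcels in 4
    networks, 12 subjects with one AP/PA scan pair each, 300 timepoints,
    SNR 5, and subject misalignments of at most 5 degrees.
    """

    mesh_subdivisions: int = 3
    n_parcels: int = 20
    n_networks: int = 4
    n_subjects: int = 12
    sessions_per_visit: int = 1
    phase_encodings: tuple = ("AP", "PA")
    timepoints: int = 300
    snr: float = 5.0
    within_parcel_coherence: float = 0.95
    network_coupling: float = 0.6
    misalignment_deg: float = 5.0
    medial_cap_frac: float = 0.05
    ar_rho: float = 0.3
    tr_seconds: float = 0.8
    age_groups_months: tuple = DEFAULT_AGE_GROUPS_MONTHS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_parcels", "n_networks", "n_subjects", "timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass(eq=False)
class SyntheticCohort:
    """Scans plus ground truth for recovery scoring."""

    spec: SyntheticCohortSpec
    mesh: TriangleMesh
    truth_parcellation: Parcellation
    network_labels: np.ndarray
    scans: list = field(default_factory=list)
    metadata: pd.DataFrame | None = None
    subject_warps: dict = field(default_factory=dict)
    subject_vertex_parcels: dict = field(default_factory=dict)


def synth_timeseries(
    mesh: TriangleMesh,
    parc: Parcellation,
    network_labels: np.ndarray,
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    vertex_parcels: np.ndarray | None = None,
    **scan_meta,
) -> ScanTimeSeries:
    """One scan's vertex x time BOLD-like matrix under the planted model.

    ``vertex_parcels`` overrides the vertex -> parcel assignment (used to
    apply a subject's misalignment warp); medial-wall rows are NaN.
    """
    T = spec.timepoints
    P = parc.n_parcels
    K = int(np.max(network_labels))
    h = _ar1(rng, (K, T), spec.ar_rho)
    u = _ar1(rng, (P, T), spec.ar_rho)
    w = spec.network_coupling
    s = np.sqrt(w) * h[network_labels - 1] + np.sqrt(1.0 - w) * u  # (P, T)
    labels = parc.labels if vertex_parcels is None else vertex_parcels
    V = mesh.n_vertices
    c = spec.within_parcel_coherence
    z = _ar1(rng, (V, T), spec.ar_rho)
    data = np.full((V, T), np.nan)
    cortex = labels > 0
    data[cortex] = spec.snr * (
        np.sqrt(c) * s[labels[cortex] - 1] + np.sqrt(1.0 - c) * z[cortex]
    ) + rng.standard_normal((int(cortex.sum()), T))
    return ScanTimeSeries(data, tr_seconds=spec.tr_seconds, **scan_meta)


def warp_vertex_parcels(
    mesh: TriangleMesh, parc: Parcellation, positions: np.ndarray
) -> np.ndarray:
    """Vertex -> parcel assignment after displacing vertices to ``positions``.

    Each vertex takes the label of the nearest cortical vertex to its
    displaced position; medial-wall vertices stay 0.
    """
    cortex = np.where(mesh.cortex_mask)[0]
    tree = cKDTree(mesh.sphere_coords[cortex])
    _, near = tree.query(positions)
    labels = parc.labels[cortex][near]
    labels[mesh.medial_wall] = 0
    return labels


def synth_cohort(spec: SyntheticCohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Full cohort: mesh, ground truth, scans, and a metadata table.

    Subjects are spread over the age groups round-robin; each subject has
    one visit with ``sessions_per_visit`` sessions of one scan per phase
    encoding.  Deterministic given (spec, seed).
    """
    seed = spec.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mesh = icosphere(
        spec.mesh_subdivisions, medial_cap_frac=spec.medial_cap_frac
    )
    parc = synth_parcellation(mesh, spec.n_parcels, rng)
    networks = synth_network_labels(spec.n_parcels, spec.n_networks, rng)
    cohort = SyntheticCohort(spec, mesh, parc, networks)
    rows = []
    groups = spec.age_groups_months
    for i in range(spec.n_subjects):
        sid = f"sub{i:03d}"
        month = groups[i % len(groups)]
        age = int(round(month * DAYS_PER_MONTH + rng.uniform(-15, 15)))
        pos = random_smooth_warp(mesh, spec.misalignment_deg, rng)
        vparc = warp_vertex_parcels(mesh, parc, pos)
        cohort.subject_warps[sid] = pos
        cohort.subject_vertex_parcels[sid] = vparc
        visit = f"{sid}_v1"
        for s in range(spec.sessions_per_visit):
            sess = f"{visit}_s{s + 1}"
            for pe in spec.phase_encodings:
                ts = synth_timeseries(
                    mesh, parc, networks, spec, rng,
                    vertex_parcels=vparc,
                    phase_encoding=pe, subject_id=sid, session_id=sess,
                    visit_id=visit, age_days=age,
                )
                scan_id = f"{sess}_{pe}"
                cohort.scans.append(ts)
                rows.append(
                    {
                        "scan_id": scan_id,
                        "subject_id": sid,
                        "session_id": sess,
                        "visit_id": visit,
                        "age_days": age,
                        "age_group": f"{month}M",
                        "phase_encoding": pe,
                    }
                )
    cohort.metadata = pd.DataFrame(rows)
    return cohort


def parcellation_gradient_field(
    parc: Parcellation,
    mesh: TriangleMesh,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic gradient field whose watershed basins are the parcels.

    Low inside parcels, ridged at parcel borders (value decays with graph
    distance from the nearest other-parcel vertex); optional additive noise.
    Handy for planted-basin watershed tests without a full pipeline run.
    """
    labels = parc.labels
    border_adjacent = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        if labels[v] <= 0:
            continue
        for u in mesh.neighbor_lists[v]:
            lu = labels[int(u)]
            if lu > 0 and lu != labels[v]:
                border_adjacent[v] = True
                break
    graph = _edge_weighted_graph(mesh)
    dist = dijkstra(graph, indices=np.where(border_adjacent)[0], directed=False, min_only=True)
    scale = 2.0 * mesh.mean_edge_length
    field = np.exp(-dist / scale)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        field = field + noise_sd * rng.standard_normal(mesh.n_vertices)
    field[mesh.medial_wall] = np.nan
    return field
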