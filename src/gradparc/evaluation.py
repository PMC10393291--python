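"""Evaluation battery for local gradient maps and parcellations.

Implements the standard quality checks for gradient-based parcellations:

* split-half reproducibility — random 'generating'/'repeating' halves of the
  cohort, maps binarized to their top 25% of local gradient, overlap scored
  with the Dice ratio, repeated (1000 times by default);
* parcel homogeneity — percent variance of a parcel's vertex connectivity
  profiles explained by their first principal component;
* parcel variance — sum over profile dimensions of the standard deviation
  across a parcel's vertices, averaged over parcels for a map-level score;
* rotation null parcellations — the real parcellation rigidly rotated by
  random x/y/z angles (1000 by default), preserving parcel number, size and
  shape, the reference distribution for homogeneity/variance significance;
* spherical Hausdorff distance between border sets, in mm;
* patch-correlation variability between two local gradient maps:
  Var(v) = 0.5 * (1 - corr(p1, p2)) over 10-ring patches around v.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .gradient import binarize_top  # noqa: F401  (canonical home re-exported here)
from .mesh import ScalarMap, TriangleMesh, geodesic_sphere_distance, nanmean_quiet
from .parcellation import Parcellation

DEFAULT_REPRO_FRAC = 0.25
DEFAULT_N_REPETITIONS = 1000
DEFAULT_N_NULLS = 1000
DEFAULT_VARIABILITY_RING = 10
MEDIAL_WALL_OVERLAP_FRAC = 0.5  # parcel counts as "in the wall" at >= 50%


@dataclass(eq=False)
class VariabilityMap(ScalarMap):
    """Patch-correlation variability between two maps; values in [0, 1]."""

    ring: int = DEFAULT_VARIABILITY_RING


@dataclass(eq=False)
class NullEnsemble:
    """Rotation-null versions of a parcellation.

    ``labels[i]`` is the i-th null's per-vertex parcel labels after
    nearest-vertex resampling; ``wall_flags[i, p-1]`` marks parcel p rotated
    (>= 50% of its vertices) into the medial wall in null i.
    """

    parcellation: Parcellation
    rotations: np.ndarray  # (n, 3) x/y/z angles
    labels: np.ndarray  # (n, V) int
    wall_flags: np.ndarray  # (n, P) bool
    rng_seed: int | None = None

    @property
    def n(self) -> int:
        return self.labels.shape[0]


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary maps.

    Two empty sets are defined as perfectly overlapping (1.0).
    """
    av = a.values if isinstance(a, ScalarMap) else np.asarray(a, float)
    bv = b.values if isinstance(b, ScalarMap) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("maps differ in length")
    aset = av == 1
    bset = bv == 1
    denom = aset.sum() + bset.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.sum(aset & bset) / denom


def split_half_reproducibility(
    subject_maps,
    n_rep: int = DEFAULT_N_REPETITIONS,
    frac: float = DEFAULT_REPRO_FRAC,
    rng: np.random.Generator | int | None = None,
):
    """Distribution of split-half Dice ratios of binarized group maps.

    Each repetition randomly splits the subject maps into disjoint halves,
    averages each half, binarizes both averages to their top ``frac`` and
    scores the Dice overlap.  Returns ``(mean, sd, samples)``.
    """
    maps = list(subject_maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mesh = maps[0].mesh
    arr = np.stack([m.values for m in maps])
    n = len(maps)
    half = n // 2
    samples = np.empty(n_rep)
    for i in range(n_rep):
        perm = rng.permutation(n)
        g = np.nanmean(arr[perm[:half]], axis=0)
        r = np.nanmean(arr[perm[half:]], axis=0)
        bg = binarize_top(ScalarMap(g, mesh), frac)
        br = binarize_top(ScalarMap(r, mesh), frac)
        samples[i] = dice(bg, br)
    return float(samples.mean()), float(samples.std(ddof=1)), samples


# ---------------------------------------------------------------------------
# homogeneity / variance
# ---------------------------------------------------------------------------

def _parcel_label_info(parc_or_labels, n_parcels=None):
    if isinstance(parc_or_labels, Parcellation):
        return parc_or_labels.labels, parc_or_labels.n_parcels
    labels = np.asarray(parc_or_labels, dtype=np.int64)
    if n_parcels is None:
        n_parcels = int(labels.max()) if labels.size else 0
    return labels, n_parcels


def parcel_homogeneity(parc, vertex_profiles: np.ndarray, n_parcels: int | None = None) -> np.ndarray:
    """Percent variance explained by the first PC, per parcel.

    ``vertex_profiles`` is (V, D): one connectivity profile per vertex
    (subject-mean correlation profiles).  The decomposition is the
    uncentered SVD of the profile matrix, so the score measures how much of
    the profiles is one shared component.  Single-vertex parcels return 100
    by convention.
    ``parc`` may be a Parcellation or a raw label array (as produced by the
    rotation nulls, where some parcel ids may be absent -> NaN).
    """
    labels, P = _parcel_label_info(parc, n_parcels)
    profiles = np.asarray(vertex_profiles, dtype=float)
    out = np.full(P, np.nan)
    for pid in range(1, P + 1):
        rows = profiles[labels == pid]
        rows = rows[np.isfinite(rows).all(axis=1)]
        out[pid - 1] = _largest_pc_pct(rows)
    return out


def _largest_pc_pct(rows: np.ndarray) -> float:
    # uncentered SVD: the first component is the parcel's shared profile, so
    # identical profiles give 100 and a parcel mixing two distinct profile
    # clusters scores low; mean-centering would invert that (the cluster
    # separation itself becomes the dominant component)
    if rows.shape[0] == 0:
        return np.nan
    if rows.shape[0] == 1:
        return 100.0
    s = np.linalg.svd(rows, compute_uv=False)
    total = np.sum(s**2)
    if total == 0:
        return 100.0  # all-zero profiles are trivially identical
    return float(100.0 * s[0] ** 2 / total)


def parcel_variance(parc, z_profiles: np.ndarray, n_parcels: int | None = None):
    """Profile-variability per parcel and its parcellation-level mean.

    ``z_profiles`` is (V, D): subject-average z-scored connectivity profile
    per vertex.  For each parcel the vertex profiles form a D x n matrix
    (columns = vertices); the parcel value is the sum over rows of the
    standard deviation across columns.  Single-vertex parcels are 0.
    ``parc`` may be a Parcellation or a raw label array.  Returns
    ``(per_parcel, mean_over_parcels)``.
    """
    labels, P = _parcel_label_info(parc, n_parcels)
    profiles = np.asarray(z_profiles, dtype=float)
    out = np.full(P, np.nan)
    for pid in range(1, P + 1):
        rows = profiles[labels == pid]
        rows = rows[np.isfinite(rows).all(axis=1)]
        if rows.shape[0] == 0:
            continue
        if rows.shape[0] == 1:
            out[pid - 1] = 0.0
            continue
        out[pid - 1] = float(np.sum(np.std(rows, axis=0, ddof=0)))
    return out, float(nanmean_quiet(out))


# ---------------------------------------------------------------------------
# rotation nulls
# ---------------------------------------------------------------------------

def generate_null_parcellations(
    parc: Parcellation,
    mesh: TriangleMesh,
    n: int = DEFAULT_N_NULLS,
    rng: np.random.Generator | int | None = None,
) -> NullEnsemble:
    """Rotation-null ensemble of a parcellation.

    Each null applies one random rigid rotation (independent uniform angles
    about x, y and z, applied in that order) to the whole parcellation and
    resamples labels to the nearest vertex, keeping parcel number and (up to
    resampling) parcel sizes.  Parcels with >= 50% of their vertices landing
    on the medial wall are flagged; their metrics are not evaluated in that
    null.
    """
    if n < 1:
        raise ValueError("need at least one null")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    V = mesh.n_vertices
    P = parc.n_parcels
    tree = cKDTree(mesh.sphere_coords)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n, 3))
    labels = np.zeros((n, V), dtype=np.int32)
    wall_flags = np.zeros((n, P), dtype=bool)
    for i in range(n):
        rot = Rotation.from_euler("xyz", angles[i]).as_matrix()
        # label of the rotated parcellation at each vertex = original label
        # at the nearest pre-rotation position of that vertex
        _, src = tree.query(mesh.sphere_coords @ rot)  # inverse rotation
        lab = parc.labels[src].astype(np.int32)
        lab[mesh.medial_wall] = 0  # no data on the wall
        # wall detection uses the forward map of each parcel's vertices
        _, dst = tree.query(mesh.sphere_coords @ rot.T)
        for pid in range(1, P + 1):
            members = np.where(parc.labels == pid)[0]
            landed = dst[members]
            frac_wall = np.mean(mesh.medial_wall[landed])
            if frac_wall >= MEDIAL_WALL_OVERLAP_FRAC:
                wall_flags[i, pid - 1] = True
                lab[lab == pid] = 0
        labels[i] = lab
    return NullEnsemble(parc, angles, labels, wall_flags, rng_seed=seed)


def null_parcel_metrics(
    ensemble: NullEnsemble, metric_fn
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a per-parcel metric on every null of an ensemble.

    ``metric_fn(parcellation) -> (P,) array`` is called on each null
    parcellation (medial-wall-flagged parcels are NaN there).  Returns
    ``(per_null, per_parcel_mean)`` where ``per_parcel_mean[p]`` averages
    parcel p over the nulls in which it stayed on the cortex.
    """
    mesh = ensemble.parcellation.mesh
    P = ensemble.parcellation.n_parcels
    per_null = np.full((ensemble.n, P), np.nan)
    for i in range(ensemble.n):
        lab = ensemble.labels[i].astype(np.int64)
        vals = metric_fn(lab)
        vals = np.asarray(vals, dtype=float)
        vals[ensemble.wall_flags[i]] = np.nan
        per_null[i] = vals
    with np.errstate(invalid="ignore"):
        per_parcel = np.nanmean(per_null, axis=0)
    return per_null, per_parcel


def null_comparison(real_value: float, null_values, direction: str) -> float:
    """Rank-based one-sided p-value of a real metric against its nulls.

    ``direction='greater'`` tests whether the real value is higher than the
    nulls (counts nulls >= real); ``'less'`` the opposite.  Uses the
    add-one permutation formula (1 + #beyond) / (1 + n).
    """
    nulls = np.asarray(list(null_values), dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise ValueError("no null values")
    if direction == "greater":
        beyond = np.sum(nulls >= real_value)
    elif direction == "less":
        beyond = np.sum(nulls <= real_value)
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return float((1 + beyond) / (1 + nulls.size))


# ---------------------------------------------------------------------------
# border distances & variability
# ---------------------------------------------------------------------------

def hausdorff_spherical(borders_a, borders_b, mesh: TriangleMesh) -> float:
    """Hausdorff distance (mm) between two vertex sets on the sphere."""
    a = np.asarray(sorted(borders_a), dtype=np.int64)
    b = np.asarray(sorted(borders_b), dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("border sets must be nonempty")
    pa = mesh.sphere_coords[a]
    pb = mesh.sphere_coords[b]
    d = geodesic_sphere_distance(pa[:, None, :], pb[None, :, :], mesh.radius)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def variability_between(
    g1: ScalarMap,
    g2: ScalarMap,
    mesh: TriangleMesh,
    ring: int = DEFAULT_VARIABILITY_RING,
) -> VariabilityMap:
    """Patch-correlation variability map between two local gradient maps.

    Per vertex v: over the ``ring``-neighborhood patch P_v, extract the two
    maps' value vectors p1, p2 (defined vertices only) and score
    0.5 * (1 - Pearson(p1, p2)), in [0, 1].  Vertices whose patch has fewer
    than 3 defined values, or a constant patch in either map (correlation
    undefined), are NaN.
    """
    ringmat = mesh.k_ring_matrix(ring).tocsr()
    v1 = g1.values
    v2 = g2.values
    defined = np.isfinite(v1) & np.isfinite(v2) & mesh.cortex_mask
    out = np.full(mesh.n_vertices, np.nan)
    for v in np.where(mesh.cortex_mask)[0]:
        patch = ringmat.indices[ringmat.indptr[v]: ringmat.indptr[v + 1]]
        patch = patch[defined[patch]]
        if patch.size < 3:
            continue
        p1 = v1[patch]
        p2 = v2[patch]
        s1 = p1.std()
        s2 = p2.std()
        if s1 == 0 or s2 == 0:
            continue
        r = float(np.mean((p1 - p1.mean()) * (p2 - p2.mean())) / (s1 * s2))
        out[v] = 0.5 * (1.0 - np.clip(r, -1.0, 1.0))
    return VariabilityMap(out, mesh, ring=ring, name="variability")
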