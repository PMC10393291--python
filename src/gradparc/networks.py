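"""Parcel-level functional network discovery and stability analysis.

Per subject, parcel mean time courses are correlated pairwise and the top
10% of the correlations are kept as unit edges, so every subject contributes
the same number of connections; the subject binaries are averaged into a
group connectivity matrix.  Parcels are grouped into networks by clustering
their row-normalized connectivity profiles with spherical (cosine) k-means,
restarted and best-objective kept — the documented stand-in for a mixture
model over connectivity profiles.  The number of networks k is explored via
random split-half stability: two half-cohort clusterings compared with an
Amari-type similarity, averaged over repetitions (200 by default, k in
[2, 30]); the curve is reported, candidate peaks are never auto-selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import rowwise_pearson
from .parcellation import Parcellation

DEFAULT_EDGE_FRAC = 0.10
DEFAULT_K_RANGE = (2, 30)
DEFAULT_N_REP = 200
DEFAULT_N_RESTARTS = 50


@dataclass(eq=False)
class ParcelConnectivity:
    """n x n parcel connectivity; weights, a subject binary, or a group mean."""

    matrix: np.ndarray
    parcel_ids: np.ndarray
    level: str = "subject"  # subject | group

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("parcel connectivity must be square")
        self.matrix = m
        self.parcel_ids = np.asarray(self.parcel_ids)

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass(eq=False)
class NetworkClustering:
    """Parcel -> network assignment from one clustering run."""

    labels: np.ndarray  # values in 1..k
    k: int
    rng_seed: int | None = None
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")


@dataclass(eq=False)
class StabilityCurve:
    """Mean split-half stability per candidate network count k."""

    k_values: np.ndarray
    stability: np.ndarray
    n_rep: int

    def argmax_k(self) -> int:
        return int(self.k_values[int(np.argmax(self.stability))])


# ---------------------------------------------------------------------------
# parcel time courses and group connectivity
# ---------------------------------------------------------------------------

def parcel_mean_timecourses(ts, parc: Parcellation) -> np.ndarray:
    """Unweighted vertex-mean time course per parcel, (n_parcels, T).

    Border and medial-wall vertices are excluded; a parcel with no usable
    vertices yields a NaN row.
    """
    data = ts.data if hasattr(ts, "data") else np.asarray(ts, float)
    if data.shape[0] != parc.mesh.n_vertices:
        raise ValueError("time series not on the parcellation's mesh")
    out = np.full((parc.n_parcels, data.shape[1]), np.nan)
    for pid in parc.parcel_ids:
        rows = data[parc.parcel_vertices(pid)]
        rows = rows[np.isfinite(rows).all(axis=1)]
        if rows.shape[0]:
            out[pid - 1] = rows.mean(axis=0)
    return out


def _binarize_top_edges(corr: np.ndarray, frac: float = DEFAULT_EDGE_FRAC) -> np.ndarray:
    """Keep the top ``frac`` of off-diagonal upper-triangle correlations.

    The kept count is ceil(frac * n_valid_pairs); ties at the cutoff break
    by pair index.  Pairs involving undefined parcels are excluded from the
    pool and stay 0.  Returns a symmetric 0/1 matrix with zero diagonal.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    valid = np.isfinite(vals)
    pool = np.where(valid)[0]
    m = int(np.ceil(frac * pool.size))
    order = np.lexsort((pool, -vals[pool]))
    keep = pool[order[:m]]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = 1.0
    out += out.T
    return out


def group_binary_connectivity(
    subject_ts, parc: Parcellation, edge_frac: float = DEFAULT_EDGE_FRAC
) -> ParcelConnectivity:
    """Mean of per-subject top-``edge_frac``-binarized parcel correlations."""
    mats = []
    for ts in subject_ts:
        tc = parcel_mean_timecourses(ts, parc)
        corr = rowwise_pearson(tc, tc)
        np.fill_diagonal(corr, np.nan)
        mats.append(_binarize_top_edges(corr, edge_frac))
    if not mats:
        raise ValueError("need at least one subject")
    group = np.mean(mats, axis=0)
    return ParcelConnectivity(group, parc.parcel_ids, level="group" if len(mats) > 1 else "subject")


# ---------------------------------------------------------------------------
# spherical k-means clustering
# ---------------------------------------------------------------------------

def _spherical_kmeans_once(x: np.ndarray, k: int, rng: np.random.Generator):
    n = x.shape[0]
    centers = x[rng.choice(n, size=k, replace=False)]
    labels = np.zeros(n, dtype=np.int64)
    for it in range(100):
        sim = x @ centers.T
        new_labels = np.argmax(sim, axis=1)
        # re-seed empty clusters with the worst-fit point
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(sim[np.arange(n), new_labels]))
                new_labels[worst] = c
        if it > 0 and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            v = x[labels == c].sum(axis=0)
            nv = np.linalg.norm(v)
            centers[c] = v / nv if nv > 0 else centers[c]
    objective = float(np.sum((x @ centers.T)[np.arange(n), labels]))
    return labels, objective


def cluster_parcels(
    group_matrix,
    k: int,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> NetworkClustering:
    """Spherical k-means on row-normalized parcel connectivity profiles.

    ``n_restarts`` random initializations; the highest cosine objective
    wins, so the kept objective never worsens as restarts accumulate.
    Deterministic under a fixed seed.
    """
    m = group_matrix.matrix if hasattr(group_matrix, "matrix") else np.asarray(group_matrix, float)
    n = m.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.where(np.isfinite(m), m, 0.0).copy()
    np.fill_diagonal(x, 0.0)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    x = x / norms
    best_labels, best_obj = None, -np.inf
    for _ in range(max(1, n_restarts)):
        labels, obj = _spherical_kmeans_once(x, k, rng)
        if obj > best_obj:
            best_labels, best_obj = labels, obj
    return NetworkClustering(best_labels + 1, k=k, rng_seed=seed, objective=best_obj)


# ---------------------------------------------------------------------------
# Amari-type similarity and stability
# ---------------------------------------------------------------------------

def amari_similarity(c1: NetworkClustering, c2: NetworkClustering) -> float:
    """Permutation-invariant similarity of two clusterings, in [0, 1].

    From the k x k confusion matrix Q (parcel counts), the Amari-type index
    averages the row-wise and column-wise mismatch 1 - max/sum; similarity
    is 1 minus that index.  Equals 1 iff the partitions are identical (up to
    label permutation); rows/columns of unused labels are skipped.
    """
    if c1.labels.shape != c2.labels.shape:
        raise ValueError("clusterings cover different parcel sets")
    if c1.k != c2.k:
        raise ValueError("clusterings must share k")
    k = c1.k
    q = np.zeros((k, k))
    for a, b in zip(c1.labels, c2.labels):
        q[a - 1, b - 1] += 1
    row_sums = q.sum(axis=1)
    col_sums = q.sum(axis=0)
    row_terms = 1.0 - q.max(axis=1)[row_sums > 0] / row_sums[row_sums > 0]
    col_terms = 1.0 - q.max(axis=0)[col_sums > 0] / col_sums[col_sums > 0]
    index = 0.5 * (row_terms.mean() + col_terms.mean())
    return float(1.0 - index)


def _subject_binaries(subject_ts, parc, edge_frac):
    out = []
    for ts in subject_ts:
        tc = parcel_mean_timecourses(ts, parc)
        corr = rowwise_pearson(tc, tc)
        np.fill_diagonal(corr, np.nan)
        out.append(_binarize_top_edges(corr, edge_frac))
    return out


def stability_curve(
    subject_ts,
    parc: Parcellation,
    k_range: tuple = DEFAULT_K_RANGE,
    n_rep: int = DEFAULT_N_REP,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    edge_frac: float = DEFAULT_EDGE_FRAC,
) -> StabilityCurve:
    """Random split-half stability of network clustering across k.

    Per repetition, subjects are split into two folds, each fold's group
    matrix is clustered for every k in ``k_range`` (inclusive), and the two
    clusterings are compared with :func:`amari_similarity`; stabilities are
    averaged over ``n_rep`` repetitions.
    """
    subject_ts = list(subject_ts)
    if len(subject_ts) < 4:
        raise ValueError("need at least 4 subjects for split halves")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    binaries = _subject_binaries(subject_ts, parc, edge_frac)
    ks = np.arange(k_range[0], k_range[1] + 1)
    acc = np.zeros(len(ks))
    n = len(binaries)
    half = n // 2
    for _ in range(n_rep):
        perm = rng.permutation(n)
        g1 = ParcelConnectivity(
            np.mean([binaries[i] for i in perm[:half]], axis=0), parc.parcel_ids, "group"
        )
        g2 = ParcelConnectivity(
            np.mean([binaries[i] for i in perm[half:]], axis=0), parc.parcel_ids, "group"
        )
        for j, k in enumerate(ks):
            c1 = cluster_parcels(g1, int(k), rng, n_restarts=n_restarts)
            c2 = cluster_parcels(g2, int(k), rng, n_restarts=n_restarts)
            acc[j] += amari_similarity(c1, c2)
    return StabilityCurve(ks, acc / n_rep, n_rep=n_rep)


# ---------------------------------------------------------------------------
# assignment reproducibility
# ---------------------------------------------------------------------------

def _align_labels(reference: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximum-overlap relabeling of ``labels`` onto ``reference``."""
    overlap = np.zeros((k, k))
    for r, l in zip(reference, labels):
        overlap[l - 1, r - 1] += 1
    mapping = np.zeros(k, dtype=np.int64)
    used_src, used_dst = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-overlap, axis=None), overlap.shape))[0]
    for src, dst in order:
        if src in used_src or dst in used_dst:
            continue
        mapping[src] = dst + 1
        used_src.add(int(src))
        used_dst.add(int(dst))
    for src in range(k):
        if src not in used_src:
            dst = next(d for d in range(k) if d not in used_dst)
            mapping[src] = dst + 1
            used_dst.add(dst)
    return mapping[labels - 1]


def assignment_reproducibility(
    subject_ts,
    parc: Parcellation,
    k: int,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    edge_frac: float = DEFAULT_EDGE_FRAC,
) -> np.ndarray:
    """Per-parcel frequency of keeping its network label under bootstrap.

    Subjects are resampled with replacement, the group matrix re-clustered,
    labels aligned to the full-cohort reference clustering by greedy maximum
    overlap, and each parcel scores the fraction of runs with an unchanged
    assignment.
    """
    subject_ts = list(subject_ts)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    binaries = _subject_binaries(subject_ts, parc, edge_frac)
    ref_group = ParcelConnectivity(np.mean(binaries, axis=0), parc.parcel_ids, "group")
    reference = cluster_parcels(ref_group, k, rng, n_restarts=n_restarts).labels
    n = len(binaries)
    same = np.zeros(parc.n_parcels)
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        g = ParcelConnectivity(
            np.mean([binaries[i] for i in take], axis=0), parc.parcel_ids, "group"
        )
        c = cluster_parcels(g, k, rng, n_restarts=n_restarts)
        aligned = _align_labels(reference, c.labels, k)
        same += aligned == reference
    return same / n_boot
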