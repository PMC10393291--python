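"""Parcel-wise developmental metrics: local efficiency and age trajectories.

Node local efficiency measures functional segregation: for a node i whose
neighbors (connections above a threshold) induce the subgraph G_i,

    Elocal(i) = 1 / (N_Gi (N_Gi - 1)) * sum_{j != k in G_i} 1 / L_{j,k}

with L the shortest path length (steps) inside G_i and unreachable pairs
contributing 0.  Because efficiency depends on connection density, the
threshold is swept from keeping 50% of connections down to 5% in 1% steps
and the area under the curve (trapezoidal, normalized by the grid span)
summarizes each node.

Sliding age windows pool scans for trajectory estimation: windows centered
at whole months, 90 days wide (+/- 45) at 2 months, widening by 4 days per
month.  A scan belongs to every window whose closed interval contains its
age, so consecutive windows overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import rowwise_pearson
from .evaluation import parcel_homogeneity
from .networks import _binarize_top_edges, parcel_mean_timecourses
from .parcellation import Parcellation

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.50, 0.05 - 1e-9, -0.01), 2)  # 46 fracs
WINDOW_BASE_DAYS = 90
WINDOW_GROWTH_DAYS_PER_MONTH = 4
WINDOW_BASE_MONTH = 2
WINDOW_LAST_MONTH = 24
DAYS_PER_MONTH = 365.25 / 12.0


@dataclass
class AgeWindow:
    """One sliding age window: center (months), width (days), member scans."""

    center_months: int
    width_days: float
    scan_indices: list = field(default_factory=list)

    @property
    def center_days(self) -> float:
        return self.center_months * DAYS_PER_MONTH

    def contains(self, age_days: float) -> bool:
        half = self.width_days / 2.0
        return self.center_days - half <= age_days <= self.center_days + half


@dataclass(eq=False)
class EfficiencyResult:
    """Per-parcel local efficiency AUC over the threshold sweep."""

    auc: np.ndarray
    threshold_grid: np.ndarray
    per_threshold: np.ndarray  # (n_thresholds, n_parcels)


def node_local_efficiency(conn, node: int, threshold_frac: float) -> float:
    """Local efficiency of one node at one connection-retention fraction.

    The weighted matrix is binarized by keeping the top ``threshold_frac``
    of off-diagonal connections (ties by pair index); G_i is the subgraph
    induced by node i's neighbors; unreachable pairs contribute 0; nodes
    with fewer than 2 neighbors score 0 by convention.
    """
    m = conn.matrix if hasattr(conn, "matrix") else np.asarray(conn, float)
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
        raise ValueError("connectivity must be symmetric")
    mm = m.copy().astype(float)
    np.fill_diagonal(mm, np.nan)
    binary = _binarize_top_edges(mm, threshold_frac)
    return _node_efficiency_binary(binary, node)


def _node_efficiency_binary(binary: np.ndarray, node: int) -> float:
    neighbors = np.where(binary[node] > 0)[0]
    n_g = neighbors.size
    if n_g < 2:
        return 0.0
    sub = binary[np.ix_(neighbors, neighbors)]
    lengths = shortest_path(csr_matrix(sub), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / lengths
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n_g * (n_g - 1)))


def local_efficiency_all_nodes(binary: np.ndarray) -> np.ndarray:
    return np.array([_node_efficiency_binary(binary, i) for i in range(binary.shape[0])])


def auc_local_efficiency(
    conn, node: int | None = None, fracs: np.ndarray = DEFAULT_THRESHOLD_GRID
) -> EfficiencyResult | float:
    """Threshold-sweep AUC of local efficiency.

    Sweeps the retention fraction over ``fracs`` (default 0.50 down to 0.05
    in 0.01 steps, 46 points), computes local efficiency at each, and
    integrates with the trapezoid rule normalized by the grid span so the
    result is a density in [0, 1].  With ``node=None`` all nodes are
    processed and an :class:`EfficiencyResult` is returned.
    """
    fracs = np.asarray(fracs, dtype=float)
    if fracs.size == 0:
        raise ValueError("empty threshold grid")
    if fracs.size > 1 and np.any(np.diff(fracs) >= 0):
        raise ValueError("threshold grid must be strictly decreasing")
    m = conn.matrix if hasattr(conn, "matrix") else np.asarray(conn, float)
    n = m.shape[0]
    mm = m.copy().astype(float)
    np.fill_diagonal(mm, np.nan)
    per = np.empty((fracs.size, n))
    for t, f in enumerate(fracs):
        binary = _binarize_top_edges(mm, f)
        per[t] = local_efficiency_all_nodes(binary)
    span = fracs[0] - fracs[-1]
    if fracs.size == 1 or span == 0:
        auc = per[0].copy()
    else:
        # integrate over increasing fraction for a positive area
        auc = np.trapezoid(per[::-1], x=fracs[::-1], axis=0) / span
    if node is not None:
        return float(auc[node])
    return EfficiencyResult(auc, fracs, per)


# ---------------------------------------------------------------------------
# sliding windows and trajectories
# ---------------------------------------------------------------------------

def window_width_days(month: int) -> float:
    """Window width in days at a given center month: 90 + 4*(m - 2)."""
    return WINDOW_BASE_DAYS + WINDOW_GROWTH_DAYS_PER_MONTH * (month - WINDOW_BASE_MONTH)


def sliding_windows(scan_ages_days) -> list[AgeWindow]:
    """Assign scans to overlapping age windows (closed intervals).

    Windows are centered at whole months 2..24; a scan joins every window
    containing its age, so windows share scans.
    """
    ages = np.asarray(list(scan_ages_days), dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    windows = []
    for month in range(WINDOW_BASE_MONTH, WINDOW_LAST_MONTH + 1):
        w = AgeWindow(month, window_width_days(month))
        w.scan_indices = [i for i, a in enumerate(ages) if w.contains(a)]
        windows.append(w)
    return windows


def _scan_metric(ts, parc: Parcellation, metric: str) -> np.ndarray:
    tc = parcel_mean_timecourses(ts, parc)
    if metric == "homogeneity":
        # vertex profiles = correlation of each vertex with every parcel mean
        profiles = rowwise_pearson(ts.data, tc)
        return parcel_homogeneity(parc, profiles)
    if metric == "local_efficiency":
        corr = rowwise_pearson(tc, tc)
        res = auc_local_efficiency(corr)
        return res.auc
    raise ValueError(f"unknown metric {metric!r}")


def metric_trajectory(
    scans, parc: Parcellation, metric: str, windows: list[AgeWindow] | None = None
) -> np.ndarray:
    """Parcel x window table of windowed developmental metrics.

    ``metric`` is 'homogeneity' or 'local_efficiency', computed per scan and
    averaged (unweighted) over each window's member scans; windows with no
    scans are NaN columns.
    """
    scans = list(scans)
    if windows is None:
        windows = sliding_windows([s.age_days for s in scans])
    per_scan = np.stack([_scan_metric(s, parc, metric) for s in scans])
    out = np.full((parc.n_parcels, len(windows)), np.nan)
    for j, w in enumerate(windows):
        if w.scan_indices:
            out[:, j] = np.nanmean(per_scan[w.scan_indices], axis=0)
    return out
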