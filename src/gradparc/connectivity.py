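"""First- and second-order resting-state functional connectivity.

The boundary-mapping pipeline starts from vertex-wise BOLD time series and
builds, per scan and hemisphere:

1. RSFC — Pearson correlation of every hemisphere vertex with every
   cortical vertex (a V x 2V matrix at full scale);
2. Fisher r-to-z transformed RSFC;
3. RSFC-2nd — the correlation between the z-profiles of every pair of
   vertices within a hemisphere (V x V), whose rows change abruptly at
   areal borders;
4. within-visit averages of RSFC-2nd so every subject contributes equally
   regardless of its scan count.

Zero-variance (flat) time courses outside the medial wall make Pearson
correlation undefined; such vertices are tracked in an explicit validity
mask and propagate as NaN rather than silently becoming zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import nanmean_quiet

FISHER_CLIP = 1e-7  # |r| clipped to 1 - FISHER_CLIP before arctanh


@dataclass(eq=False)
class ScanTimeSeries:
    """Vertex x timepoint BOLD matrix for one fMRI scan.

    ``phase_encoding`` is 'AP' or 'PA'; ``age_days`` the age at scan.
    Medial-wall rows may be NaN.
    """

    data: np.ndarray
    tr_seconds: float = 0.8
    phase_encoding: str = "AP"
    subject_id: str = ""
    session_id: str = ""
    visit_id: str = ""
    age_days: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("time series must be (vertices, timepoints>=2)")
        if self.phase_encoding not in ("AP", "PA"):
            raise ValueError("phase_encoding must be 'AP' or 'PA'")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(eq=False)
class SecondOrderConnectivity:
    """Symmetric V x V second-order connectivity (RSFC-2nd) matrix."""

    matrix: np.ndarray
    hemisphere: str = "L"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("second-order connectivity must be square")
        finite = np.isfinite(m)
        sym = finite & finite.T
        if not np.allclose(m[sym & np.tri(*m.shape, dtype=bool)],
                           m.T[sym & np.tri(*m.shape, dtype=bool)], atol=1e-6):
            raise ValueError("second-order connectivity must be symmetric")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    @property
    def valid_rows(self) -> np.ndarray:
        return np.isfinite(self.matrix).any(axis=1)


def _standardize_rows(data: np.ndarray) -> np.ndarray:
    """Rows to zero mean / unit norm; zero-variance rows become NaN rows."""
    data = np.asarray(data, dtype=float)
    centered = data - nanmean_quiet(data, axis=1, keepdims=True)
    norm = np.sqrt(np.sum(centered * centered, axis=1, keepdims=True))
    bad = (norm[:, 0] == 0) | ~np.isfinite(norm[:, 0])
    norm[bad] = np.nan
    return centered / norm


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``.

    Undefined rows (zero variance or non-finite) yield NaN rows/columns.
    """
    if a.shape[1] != b.shape[1]:
        raise ValueError("row length mismatch")
    ra = _standardize_rows(a)
    rb = _standardize_rows(b)
    with np.errstate(invalid="ignore"):
        r = ra @ rb.T
    return np.clip(r, -1.0, 1.0, out=r)


def compute_rsfc(ts_hemi: ScanTimeSeries, ts_cortex: ScanTimeSeries) -> np.ndarray:
    """First-order RSFC: hemisphere vertices vs whole-cortex vertices.

    Returns the (V_hemi, V_cortex) Pearson matrix; at full acquisition scale
    this is the 32k x 64k RSFC matrix of one hemisphere.
    """
    if ts_hemi.n_timepoints != ts_cortex.n_timepoints:
        raise ValueError("hemisphere and cortex series must share timepoints")
    return rowwise_pearson(ts_hemi.data, ts_cortex.data)


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, clipping |r| = 1 to 1 - 1e-7 first."""
    r = np.asarray(r_matrix, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1.0 + 1e-9):
        raise ValueError("correlations outside [-1, 1]")
    clipped = np.clip(r, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    out = np.arctanh(clipped)
    out[~finite] = np.nan
    return out


def compute_second_order(
    z_matrix: np.ndarray,
    hemisphere: str = "L",
    provenance: list | None = None,
    block_size: int = 2048,
) -> SecondOrderConnectivity:
    """Correlate every pair of z-profile rows within a hemisphere.

    Row-blocked so a 32k hemisphere fits in memory; entry (i, j) is the
    Pearson correlation of z-rows i and j, the diagonal is 1 for defined
    rows, and undefined rows propagate as NaN.
    """
    z = np.asarray(z_matrix, dtype=float)
    # profiles are compared over the columns defined for every valid row
    # (medial-wall columns are undefined in all profiles and drop out)
    row_valid = np.isfinite(z).any(axis=1)
    col_valid = (
        np.isfinite(z[row_valid]).all(axis=0) if row_valid.any() else np.zeros(z.shape[1], bool)
    )
    rz = _standardize_rows(z[:, col_valid])
    V = z.shape[0]
    out = np.empty((V, V))
    for lo in range(0, V, block_size):
        hi = min(lo + block_size, V)
        with np.errstate(invalid="ignore"):
            out[lo:hi] = rz[lo:hi] @ rz.T
    np.clip(out, -1.0, 1.0, out=out)
    valid = np.isfinite(out).any(axis=1)
    idx = np.where(valid)[0]
    out[idx, idx] = 1.0
    return SecondOrderConnectivity(out, hemisphere=hemisphere, provenance=provenance or [])


def average_visit_rsfc2(
    matrices: list[SecondOrderConnectivity],
) -> SecondOrderConnectivity:
    """Element-wise mean of RSFC-2nd matrices from one visit of one subject."""
    if not matrices:
        raise ValueError("no matrices to average")
    hemis = {m.hemisphere for m in matrices}
    if len(hemis) != 1:
        raise ValueError(f"cannot average matrices from mixed hemispheres {hemis}")
    shapes = {m.matrix.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError("matrices differ in vertex count")
    stack = np.stack([m.matrix for m in matrices])
    mean = stack.mean(axis=0)
    prov = [p for m in matrices for p in m.provenance]
    return SecondOrderConnectivity(mean, hemisphere=hemis.pop(), provenance=prov)
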