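"""Surface I/O: GIFTI files and the package's plain-text matrix container.

Two interchange routes are supported everywhere:

* GIFTI — ``.surf.gii`` surfaces, ``.func.gii``/``.shape.gii`` metrics and
  ``.label.gii`` label maps, via nibabel.  Label 0 is reserved for the
  medial wall / parcel borders ("???").
* the gradparc container — a one-line versioned JSON header followed by
  row-major ``%.17g`` text values.  ``%.17g`` round-trips IEEE doubles, so
  write-then-read is bit-exact; the header carries shape, dtype and free-form
  provenance metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.gifti import GiftiDataArray, GiftiImage, GiftiLabel, GiftiLabelTable

from .mesh import DEFAULT_SPHERE_RADIUS, ScalarMap, TriangleMesh

CONTAINER_MAGIC = "#gradparc-container"
CONTAINER_VERSION = 1


class FormatError(ValueError):
    """Raised when a file cannot be parsed; message names the offending element."""


# ---------------------------------------------------------------------------
# gradparc container
# ---------------------------------------------------------------------------

def write_container(path, array, meta: dict | None = None) -> None:
    """Write a 1-D or 2-D numeric array with metadata to a text container."""
    array = np.asarray(array)
    if array.ndim not in (1, 2):
        raise ValueError("container stores 1-D or 2-D arrays")
    header = {
        "version": CONTAINER_VERSION,
        "shape": list(array.shape),
        "dtype": str(array.dtype),
        "meta": meta or {},
    }
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{CONTAINER_MAGIC} {json.dumps(header)}\n")
        rows = array.reshape(array.shape[0], -1)
        if np.issubdtype(array.dtype, np.integer) or array.dtype == bool:
            fmt = "%d"
        else:
            fmt = "%.17g"
        np.savetxt(fh, rows, fmt=fmt)


def read_container(path):
    """Read a container written by :func:`write_container`.

    Returns ``(array, meta)``.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(CONTAINER_MAGIC):
            raise FormatError(f"{path}: missing container magic header line")
        try:
            header = json.loads(first[len(CONTAINER_MAGIC):])
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON header: {exc}") from exc
        if header.get("version") != CONTAINER_VERSION:
            raise FormatError(f"{path}: unsupported container version {header.get('version')}")
        shape = tuple(header["shape"])
        dtype = np.dtype(header["dtype"])
        data = np.loadtxt(fh, dtype=dtype, ndmin=2)
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: value block has {data.size} entries, header says {shape}"
        )
    return data.reshape(shape), header.get("meta", {})


# ---------------------------------------------------------------------------
# GIFTI
# ---------------------------------------------------------------------------

def write_surface_gifti(path, coords: np.ndarray, triangles: np.ndarray) -> None:
    img = GiftiImage(
        darrays=[
            GiftiDataArray(
                np.asarray(coords, dtype=np.float32),
                intent="NIFTI_INTENT_POINTSET",
            ),
            GiftiDataArray(
                np.asarray(triangles, dtype=np.int32),
                intent="NIFTI_INTENT_TRIANGLE",
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface_gifti(path):
    """Return (coords, triangles) from a .surf.gii file."""
    img = _load_gifti(path)
    coords = _darray(img, "NIFTI_INTENT_POINTSET", path)
    tris = _darray(img, "NIFTI_INTENT_TRIANGLE", path)
    return np.asarray(coords, dtype=float), np.asarray(tris, dtype=np.int64)


def write_metric_gifti(path, values) -> None:
    """Write one or more per-vertex metric maps (columns) to .func/.shape.gii."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float32))
    img = GiftiImage(
        darrays=[GiftiDataArray(col, intent="NIFTI_INTENT_NONE") for col in values]
    )
    nib.save(img, str(path))


def read_metric_gifti(path) -> np.ndarray:
    """Read metric maps; returns (n_maps, V) float array."""
    img = _load_gifti(path)
    if not img.darrays:
        raise FormatError(f"{path}: metric file contains no data arrays")
    return np.asarray([np.asarray(d.data, dtype=float) for d in img.darrays])


def write_label_gifti(path, labels, names: dict[int, str] | None = None) -> None:
    """Write a label map with a deterministic color table; 0 == '???'."""
    labels = np.asarray(labels, dtype=np.int32)
    table = GiftiLabelTable()
    ids = sorted(set(np.unique(labels).tolist()) | {0})
    rng = np.random.default_rng(0)  # deterministic colortable
    for lab in ids:
        if lab == 0:
            gl = GiftiLabel(key=0, red=0.0, green=0.0, blue=0.0, alpha=0.0)
            gl.label = "???"
        else:
            r, g, b = rng.uniform(0.1, 0.95, size=3)
            gl = GiftiLabel(key=int(lab), red=r, green=g, blue=b, alpha=1.0)
            gl.label = (names or {}).get(int(lab), f"parcel_{lab}")
        table.labels.append(gl)
    img = GiftiImage(labeltable=table)
    img.add_gifti_data_array(
        GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32")
    )
    nib.save(img, str(path))


def read_label_gifti(path):
    """Read a label map; returns (labels, {id: name})."""
    img = _load_gifti(path)
    if not img.darrays:
        raise FormatError(f"{path}: label file contains no data arrays")
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    names = {
        int(gl.key): gl.label for gl in img.labeltable.labels
    } if img.labeltable else {}
    return labels, names


def _load_gifti(path):
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad XML
        raise FormatError(f"{path}: cannot parse GIFTI file: {exc}") from exc


def _darray(img, intent: str, path):
    code = nib.nifti1.intent_codes[intent]
    for d in img.darrays:
        if d.intent == code:
            return d.data
    raise FormatError(f"{path}: no data array with intent {intent}")


# ---------------------------------------------------------------------------
# mesh bundles
# ---------------------------------------------------------------------------

def save_mesh(prefix, mesh: TriangleMesh) -> None:
    """Write a mesh as GIFTI files sharing ``prefix``.

    Emits ``<prefix>.surf.gii`` (anatomical), ``<prefix>.sphere.surf.gii``
    (spherical mapping) and ``<prefix>.medialwall.shape.gii`` (1 = wall).
    """
    prefix = str(prefix)
    write_surface_gifti(prefix + ".surf.gii", mesh.vertex_coords, mesh.triangles)
    write_surface_gifti(prefix + ".sphere.surf.gii", mesh.sphere_coords, mesh.triangles)
    write_metric_gifti(prefix + ".medialwall.shape.gii", mesh.medial_wall.astype(float))


def load_mesh(prefix, hemisphere: str = "L", radius: float | None = None) -> TriangleMesh:
    prefix = str(prefix)
    coords, tris = read_surface_gifti(prefix + ".surf.gii")
    sphere, tris2 = read_surface_gifti(prefix + ".sphere.surf.gii")
    if tris.shape != tris2.shape or not np.array_equal(tris, tris2):
        raise FormatError(f"{prefix}: surface and sphere triangulations differ")
    wall = read_metric_gifti(prefix + ".medialwall.shape.gii")[0] > 0.5
    if radius is None:
        radius = float(np.median(np.linalg.norm(sphere, axis=1)))
    # snap float32 storage back onto the sphere
    norms = np.linalg.norm(sphere, axis=1, keepdims=True)
    sphere = sphere / norms * radius
    return TriangleMesh(coords, tris, sphere, wall, hemisphere=hemisphere, radius=radius)


def save_scalar_map(path, smap: ScalarMap) -> None:
    write_metric_gifti(path, np.where(np.isfinite(smap.values), smap.values, np.nan))


def load_scalar_map(path, mesh: TriangleMesh, **kw) -> ScalarMap:
    vals = read_metric_gifti(path)[0]
    return ScalarMap(vals, mesh, **kw)
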