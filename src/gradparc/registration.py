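"""Demons-style spherical registration driven by feature maps.

Individual surfaces are aligned to a template by deforming their spherical
mapping: each mesh vertex's sphere position moves so that feature maps
(local gradient of FC, optionally cortical folding) sampled at the moved
positions match the template.  The update is a classic demons force —
feature difference times the tangent gradient of the warped feature, with
the bounded demons normalization — regularized by "fluid" smoothing of each
update and "diffusion" smoothing of the accumulated displacement, both with
spherical Gaussians.  Steps are accepted only if they decrease the weighted
feature MSE (line search by step halving), and any step that would invert a
spherical triangle is halved until none does, a cheap diffeomorphism proxy.

The group-template procedure alternates registering every map to the
current mean with re-averaging the warped maps; by default four outer
iterations, stopping early when the mean map no longer changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .gradient import LocalGradientMap, get_operator
from .mesh import ScalarMap, TriangleMesh, nanmean_quiet, smooth_vertex_field


class RegistrationError(RuntimeError):
    pass


@dataclass(eq=False)
class SphericalWarp:
    """Per-vertex re-positioning on the sphere.

    ``target_positions[v]`` is where vertex v's data is sampled from; the
    identity warp stores the mesh's own sphere coordinates exactly.
    """

    target_positions: np.ndarray
    mesh: TriangleMesh
    feature_weights: tuple = (1.0,)
    n_iterations_run: int = 0

    def __post_init__(self) -> None:
        self.target_positions = np.asarray(self.target_positions, dtype=float)
        r = np.linalg.norm(self.target_positions, axis=1)
        if np.any(np.abs(r - self.mesh.radius) > 1e-6 * self.mesh.radius):
            raise ValueError("warp target positions must lie on the sphere")

    @classmethod
    def identity(cls, mesh: TriangleMesh, **kw) -> "SphericalWarp":
        return cls(mesh.sphere_coords.copy(), mesh, **kw)

    def max_displacement(self) -> float:
        return float(
            np.max(np.linalg.norm(self.target_positions - self.mesh.sphere_coords, axis=1))
        )


@dataclass
class RegistrationParams:
    """Knobs of the demons registration; distances in mm on the sphere."""

    step_size: float = 2.0
    n_iterations: int = 30
    n_levels: int = 3
    fluid_sigma: float = 6.0
    diffusion_sigma: float = 4.0
    channel_weights: tuple | None = None
    max_halvings: int = 20
    eps: float = 1e-12


class SphereInterpolator:
    """Barycentric interpolation of vertex maps at arbitrary sphere points.

    Candidate triangles come from the nearest vertices of a KD-tree on the
    mesh sphere; barycentric weights are solved against precomputed corner
    matrices (central projection along the ray from the origin).
    """

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.sphere_coords)
        self.tri = mesh.triangles
        # inverse corner matrices: w = inv(corners.T) @ p
        corners = mesh.sphere_coords[mesh.triangles]  # (F, 3, 3)
        self._inv = np.linalg.inv(corners.transpose(0, 2, 1))
        # padded vertex -> incident triangle table
        vt = mesh.vertex_triangles
        width = max(len(t) for t in vt)
        self._vt_pad = np.zeros((mesh.n_vertices, width), dtype=np.int64)
        self._vt_mask = np.zeros((mesh.n_vertices, width), dtype=bool)
        for v, ts in enumerate(vt):
            self._vt_pad[v, : len(ts)] = ts
            self._vt_mask[v, : len(ts)] = True

    def _candidate_best(self, points, near):
        """Best candidate triangle (max of min barycentric weight) per point."""
        cand = self._vt_pad[near]  # (n, w)
        mask = self._vt_mask[near]
        w = np.einsum("ncij,nj->nci", self._inv[cand], points)  # (n, w, 3)
        s = w.sum(axis=2)
        good = mask & (s > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = w / s[..., None]
        minw = np.where(good, w.min(axis=2), -np.inf)
        best = np.argmax(minw, axis=1)
        idx = np.arange(len(points))
        return cand[idx, best], w[idx, best], minw[idx, best]

    def locate(self, points: np.ndarray, k_max: int = 12):
        """Containing triangle and clipped barycentric weights per point."""
        points = np.asarray(points, dtype=float)
        n = len(points)
        _, near = self.tree.query(points)
        tri_idx, weights, minw = self._candidate_best(points, near)
        # widen the search for points not resolved by the nearest vertex
        unresolved = np.where(minw < -1e-9)[0]
        if unresolved.size:
            k = min(k_max, self.mesh.n_vertices)
            _, nears = self.tree.query(points[unresolved], k=k)
            nears = np.atleast_2d(nears)
            for col in range(1, k):
                t2, w2, m2 = self._candidate_best(points[unresolved], nears[:, col])
                better = m2 > minw[unresolved]
                tri_idx[unresolved[better]] = t2[better]
                weights[unresolved[better]] = w2[better]
                minw[unresolved[better]] = m2[better]
                if np.all(minw[unresolved] >= -1e-9):
                    break
        bad = np.where(minw < -1e-6)[0]
        if bad.size:
            raise RegistrationError(
                f"point(s) {bad[:5].tolist()} failed containing-triangle lookup"
            )
        weights = np.clip(weights, 0.0, None)
        weights /= weights.sum(axis=1, keepdims=True)
        return tri_idx, weights

    def interpolate(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        tri_idx, w = self.locate(points)
        corner_vals = values[self.tri[tri_idx]]  # (n, 3)
        finite = np.isfinite(corner_vals)
        wf = np.where(finite, w, 0.0)
        mass = wf.sum(axis=1)
        out = np.where(
            mass > 0,
            np.nansum(wf * np.where(finite, corner_vals, 0.0), axis=1)
            / np.where(mass > 0, mass, 1.0),
            np.nan,
        )
        return out


from functools import lru_cache


@lru_cache(maxsize=8)
def _interpolator(mesh: TriangleMesh) -> SphereInterpolator:
    return SphereInterpolator(mesh)


def resample_map(smap: ScalarMap, warp: SphericalWarp, mesh: TriangleMesh) -> ScalarMap:
    """Sample a map at a warp's target positions (barycentric, convex).

    Constant maps are invariant and the output is bounded by the input's
    min/max over defined vertices.
    """
    interp = _interpolator(mesh)
    vals = interp.interpolate(smap.values, warp.target_positions)
    out = ScalarMap(vals, mesh, smoothing_sigma=smap.smoothing_sigma, name=smap.name)
    if isinstance(smap, LocalGradientMap):
        out = LocalGradientMap(
            vals,
            mesh,
            smoothing_sigma=smap.smoothing_sigma,
            name=smap.name,
            n_boundary_maps=smap.n_boundary_maps,
            group_label=smap.group_label,
        )
    return out


def _orientation_signs(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = positions[triangles[:, 0]]
    b = positions[triangles[:, 1]]
    c = positions[triangles[:, 2]]
    return np.sign(np.einsum("ij,ij->i", a, np.cross(b, c)))


def _feature_mse(stack_t, stack_w, weights, defined) -> float:
    diffs = (stack_t - stack_w)[:, defined]
    return float(np.sum(weights[:, None] * np.nan_to_num(diffs) ** 2) / diffs.shape[1])


def register_to_template(
    individual_features,
    template_features,
    mesh: TriangleMesh,
    params: RegistrationParams | None = None,
) -> SphericalWarp:
    """Align an individual's feature maps onto template feature maps.

    Feature lists are aligned channel-wise (e.g. [folding, local gradient]).
    The returned warp never increases the weighted feature MSE relative to
    the identity and never inverts a spherical triangle.
    """
    params = params or RegistrationParams()
    ind = [m if isinstance(m, ScalarMap) else ScalarMap(m, mesh) for m in individual_features]
    tmpl = [m if isinstance(m, ScalarMap) else ScalarMap(m, mesh) for m in template_features]
    if len(ind) != len(tmpl):
        raise ValueError("individual and template channel counts differ")
    C = len(ind)
    wts = np.asarray(params.channel_weights if params.channel_weights is not None else [1.0] * C, dtype=float)
    if wts.shape != (C,):
        raise ValueError("one channel weight per feature channel required")

    op = get_operator(mesh)
    interp = _interpolator(mesh)
    R = mesh.radius
    defined = mesh.cortex_mask.copy()
    for m in ind + tmpl:
        defined &= np.isfinite(m.values) | mesh.medial_wall

    stack_t = np.stack([m.values for m in tmpl])
    base_signs = _orientation_signs(mesh.sphere_coords, mesh.triangles)

    pos = mesh.sphere_coords.copy()
    stack_w = np.stack([m.values for m in ind])
    mse = _feature_mse(stack_t, stack_w, wts, defined)
    n_run = 0

    # coarse-to-fine: larger fluid smoothing and steps first
    level_scales = [2.0 ** (params.n_levels - 1 - l) for l in range(params.n_levels)]
    iters_per = int(np.ceil(params.n_iterations / params.n_levels))

    for scale in level_scales:
        fluid = params.fluid_sigma * scale
        step0 = params.step_size * scale
        for _ in range(iters_per):
            # demons force summed over channels
            force = np.zeros((mesh.n_vertices, 3))
            for c in range(C):
                # vertices currently sampling undefined territory (e.g. the
                # medial wall) exert no force this iteration
                usable = defined & np.isfinite(stack_w[c])
                diff = np.where(usable, stack_t[c] - stack_w[c], 0.0)
                grad = op.vectors(stack_w[c])
                g2 = np.einsum("ij,ij->i", grad, grad)
                denom = g2 + diff**2 + params.eps
                force += wts[c] * (diff / denom)[:, None] * grad
            force = smooth_vertex_field(mesh, force, fluid)
            nrm = np.linalg.norm(force, axis=1).max()
            if nrm < 1e-15:
                break
            force *= 1.0 / nrm  # unit max displacement, scaled by step below
            step = step0
            accepted = False
            for _ in range(params.max_halvings):
                cand = pos + step * force
                disp = cand - mesh.sphere_coords
                disp = smooth_vertex_field(mesh, disp, params.diffusion_sigma)
                cand = mesh.sphere_coords + disp
                cand *= R / np.linalg.norm(cand, axis=1, keepdims=True)
                signs = _orientation_signs(cand, mesh.triangles)
                if np.any(signs * base_signs < 0):
                    step *= 0.5
                    continue
                cand_w = np.stack(
                    [interp.interpolate(m.values, cand) for m in ind]
                )
                cand_mse = _feature_mse(stack_t, cand_w, wts, defined)
                if cand_mse < mse:
                    pos, stack_w, mse = cand, cand_w, cand_mse
                    accepted = True
                    break
                step *= 0.5
            n_run += 1
            if not accepted:
                break
        # positions already on sphere; continue to finer level

    return SphericalWarp(
        pos, mesh, feature_weights=tuple(wts.tolist()), n_iterations_run=n_run
    )


def build_group_template(
    maps,
    mesh: TriangleMesh,
    n_outer: int = 4,
    params: RegistrationParams | None = None,
    tol: float = 1e-4,
):
    """Iterative gradient-driven group template (register/resample/re-average).

    Returns ``(template, warps)``.  The default of four outer iterations
    follows the point at which the population-mean map stops changing; the
    loop also stops early when the mean map's maximum absolute change drops
    below ``tol``.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps given")
    params = params or RegistrationParams()

    def mean_of(ms):
        arr = np.stack([m.values for m in ms])
        out = nanmean_quiet(arr, axis=0)
        out[~np.isfinite(arr).any(axis=0)] = np.nan
        return out

    template_vals = mean_of(maps)
    warps = [SphericalWarp.identity(mesh) for _ in maps]
    for _ in range(n_outer):
        template = LocalGradientMap(template_vals, mesh, group_label="template")
        warped = []
        new_warps = []
        for m in maps:
            w = register_to_template([m], [template], mesh, params)
            new_warps.append(w)
            warped.append(resample_map(m, w, mesh))
        new_vals = mean_of(warped)
        change = np.nanmax(np.abs(new_vals - template_vals))
        template_vals, warps = new_vals, new_warps
        if change < tol:
            break
    template = LocalGradientMap(template_vals, mesh, group_label="template")
    return template, warps
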