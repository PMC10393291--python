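import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gradparc.gradient import LocalGradientMap
from gradparc.mesh import ScalarMap
from gradparc.registration import (
    RegistrationParams,
    SphereInterpolator,
    SphericalWarp,
    _orientation_signs,
    build_group_template,
    register_to_template,
    resample_map,
)
from gradparc.synthetic import icosphere


@pytest.fixture(scope="module")
def sphere():
    return icosphere(3)


@pytest.fixture(scope="module")
def smooth_feature(sphere):
    p = sphere.sphere_coords / sphere.radius
    return ScalarMap(np.sin(2 * p[:, 0] + 1) + np.cos(3 * p[:, 1]) + p[:, 2] ** 2, sphere)


def rotated_map(smap, mesh, degrees, axis="z"):
    rot = Rotation.from_euler(axis, degrees, degrees=True).as_matrix()
    interp = SphereInterpolator(mesh)
    return ScalarMap(interp.interpolate(smap.values, mesh.sphere_coords @ rot), mesh)


class TestResample:
    def test_identity_warp_is_identity(self, sphere, smooth_feature):
        warp = SphericalWarp.identity(sphere)
        out = resample_map(smooth_feature, warp, sphere)
        np.testing.assert_allclose(out.values, smooth_feature.values, atol=1e-12)

    def test_constant_map_invariant_under_any_warp(self, sphere, rng):
        pos = sphere.sphere_coords.copy()
        pos = np.roll(pos, 3, axis=0)  # arbitrary on-sphere positions
        warp = SphericalWarp(pos, sphere)
        const = ScalarMap(np.full(sphere.n_vertices, 1.23), sphere)
        out = resample_map(const, warp, sphere)
        np.testing.assert_allclose(out.values, 1.23, atol=1e-12)

    def test_output_bounded_by_input_range(self, sphere, smooth_feature, rng):
        pos = sphere.sphere_coords + rng.normal(0, 3, (sphere.n_vertices, 3))
        pos *= sphere.radius / np.linalg.norm(pos, axis=1, keepdims=True)
        out = resample_map(smooth_feature, SphericalWarp(pos, sphere), sphere)
        assert np.nanmin(out.values) >= np.nanmin(smooth_feature.values) - 1e-12
        assert np.nanmax(out.values) <= np.nanmax(smooth_feature.values) + 1e-12

    def test_rotated_linear_field_matches_analytic(self, sphere):
        # f(p) = p_x is linear; sampling at rotated positions equals the
        # analytically rotated field up to interpolation error
        f = ScalarMap(sphere.sphere_coords[:, 0] / sphere.radius, sphere)
        rot = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        warp = SphericalWarp(sphere.sphere_coords @ rot, sphere)
        out = resample_map(f, warp, sphere)
        expected = (sphere.sphere_coords @ rot)[:, 0] / sphere.radius
        np.testing.assert_allclose(out.values, expected, atol=5e-3)

    def test_off_sphere_warp_rejected(self, sphere):
        with pytest.raises(ValueError):
            SphericalWarp(sphere.sphere_coords * 1.01, sphere)


class TestRegister:
    def test_identity_when_already_aligned(self, sphere, smooth_feature):
        warp = register_to_template([smooth_feature], [smooth_feature], sphere)
        assert warp.max_displacement() < 1e-3 * sphere.radius

    def test_three_degree_rotation_recovered(self, sphere, smooth_feature):
        ind = rotated_map(smooth_feature, sphere, 3.0)
        mse0 = np.nanmean((ind.values - smooth_feature.values) ** 2)
        warp = register_to_template([ind], [smooth_feature], sphere)
        warped = resample_map(ind, warp, sphere)
        mse1 = np.nanmean((warped.values - smooth_feature.values) ** 2)
        assert mse1 <= 0.2 * mse0  # >= 80% feature MSE reduction

    def test_objective_never_increases_relative_to_identity(self, sphere, smooth_feature, rng):
        ind = ScalarMap(smooth_feature.values + 0.3 * rng.standard_normal(sphere.n_vertices), sphere)
        warp = register_to_template([ind], [smooth_feature], sphere)
        warped = resample_map(ind, warp, sphere)
        before = np.nanmean((ind.values - smooth_feature.values) ** 2)
        after = np.nanmean((warped.values - smooth_feature.values) ** 2)
        assert after <= before + 1e-12

    def test_no_triangle_inversion(self, sphere, smooth_feature):
        ind = rotated_map(smooth_feature, sphere, 4.0, axis="x")
        warp = register_to_template([ind], [smooth_feature], sphere)
        base = _orientation_signs(sphere.sphere_coords, sphere.triangles)
        post = _orientation_signs(warp.target_positions, sphere.triangles)
        assert np.all(base * post >= 0)

    def test_channel_count_mismatch_raises(self, sphere, smooth_feature):
        with pytest.raises(ValueError):
            register_to_template([smooth_feature], [smooth_feature] * 2, sphere)


class TestGroupTemplate:
    def test_identical_maps_give_identity_template(self, sphere, smooth_feature):
        maps = [LocalGradientMap(np.abs(smooth_feature.values) / 4, sphere) for _ in range(3)]
        template, warps = build_group_template(maps, sphere, n_outer=4)
        np.testing.assert_allclose(template.values, maps[0].values, atol=1e-6)
        assert all(w.max_displacement() < 1e-3 * sphere.radius for w in warps)

    def test_input_order_invariance(self, sphere, smooth_feature):
        maps = [
            LocalGradientMap(np.abs(rotated_map(smooth_feature, sphere, d).values) / 4, sphere)
            for d in (-2.0, 0.0, 2.0)
        ]
        params = RegistrationParams(n_iterations=6)
        t1, _ = build_group_template(maps, sphere, n_outer=1, params=params)
        t2, _ = build_group_template(maps[::-1], sphere, n_outer=1, params=params)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-10)

    def test_synthetic_recovery_halves_feature_mse(self, sphere, smooth_feature, rng):
        # 10 subjects = rotations of one pattern; smooth random warps stand in
        maps = [
            LocalGradientMap(
                np.abs(rotated_map(smooth_feature, sphere, float(rng.uniform(-4, 4)),
                                   axis="xyz"[i % 3]).values) / 4,
                sphere,
            )
            for i in range(10)
        ]
        arr = np.stack([m.values for m in maps])
        naive = arr.mean(axis=0)
        pre = np.mean([(m.values - naive) ** 2 for m in maps])
        template, warps = build_group_template(maps, sphere)
        post = np.mean(
            [(resample_map(m, w, sphere).values - template.values) ** 2
             for m, w in zip(maps, warps)]
        )
        assert post < 0.5 * pre

    def test_empty_input_raises(self, sphere):
        with pytest.raises(ValueError):
            build_group_template([], sphere)


def test_supra_resolution_misalignment_contrast(small_cohort, rng):
    """Registration sharpens the group map when misalignment exceeds the
    mesh resolution (the qualitative individual-then-register contrast)."""
    import gradparc as gp

    co = small_cohort
    sig = gp.pipeline.equivalent_smoothing_sigma(co.mesh)
    gmap, _, _ = gp.cohort_group_map(
        co.scans, co.mesh, config=gp.PipelineConfig(smoothing_sigma_mm=sig)
    )
    interp = SphereInterpolator(co.mesh)
    maps = []
    for i in range(8):
        # rotations beyond the ~17 degree edge length of the s=2 sphere
        rot = Rotation.from_euler("xyz", rng.uniform(-20, 20, 3), degrees=True).as_matrix()
        maps.append(
            LocalGradientMap(interp.interpolate(gmap.values, co.mesh.sphere_coords @ rot), co.mesh)
        )
    naive = np.nanmean(np.stack([m.values for m in maps]), axis=0)
    template, _ = build_group_template(maps, co.mesh)
    assert np.nanmax(template.values) > np.nanmax(naive)
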