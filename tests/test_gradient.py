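import numpy as np
import pytest

from gradparc.gradient import (
    DegenerateTriangleError,
    GradientOperator,
    LocalGradientMap,
    age_independent_map,
    binarize_top,
    combine_maps,
    gradient_matrix,
    local_gradient_map,
    overlap_consistency,
    spatial_gradient,
    watershed_boundary_map,
)
from gradparc.mesh import ScalarMap, TriangleMesh, geodesic_sphere_distance
from gradparc.synthetic import synth_parcellation


def lgm(values, mesh, **kw):
    return LocalGradientMap(np.asarray(values, float), mesh, **kw)


class TestSpatialGradient:
    def test_constant_map_has_zero_gradient(self, ico2_wall):
        g = spatial_gradient(ScalarMap(np.full(162, 2.2), ico2_wall), ico2_wall)
        assert np.nanmax(np.abs(g.values)) < 1e-12

    def test_shift_invariance_and_nonnegativity(self, ico2, rng):
        v = rng.random(162)
        g1 = spatial_gradient(ScalarMap(v, ico2), ico2)
        g2 = spatial_gradient(ScalarMap(v + 5.0, ico2), ico2)
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-10)
        assert np.nanmin(g1.values) >= 0

    def test_matches_least_squares_triangle_oracle(self, ico2, rng):
        # per-triangle gradient magnitude from an independent lstsq solve,
        # aggregated with the same area weights
        v = rng.random(162)
        op = GradientOperator(ico2)
        mags = np.zeros(ico2.n_triangles)
        for t, (a, b, c) in enumerate(ico2.triangles):
            p = ico2.sphere_coords
            A = np.vstack([p[b] - p[a], p[c] - p[a]])
            rhs = np.array([v[b] - v[a], v[c] - v[a]])
            g, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            mags[t] = np.linalg.norm(g)
        expected = np.asarray(op.aggregate @ mags)
        got = spatial_gradient(ScalarMap(v, ico2), ico2)
        np.testing.assert_allclose(got.values, expected, atol=1e-9)

    def test_degenerate_triangle_is_named(self, ico2):
        coords = ico2.sphere_coords.copy()
        a, b, _ = ico2.triangles[5]
        coords[b] = coords[a]  # coincident corners collapse triangle 5
        mesh = TriangleMesh(coords, ico2.triangles, coords, np.zeros(162, bool))
        with pytest.raises(DegenerateTriangleError, match="triangle"):
            spatial_gradient(ScalarMap(np.ones(162), mesh), mesh)


class TestGradientMatrix:
    def test_constant_rows_give_zero_matrix(self, ico2_wall):
        rsfc2 = np.ones((162, 162))
        g = gradient_matrix(rsfc2, ico2_wall)
        assert np.nanmax(g.matrix) < 1e-12

    def test_two_parcel_blocks_peak_on_border(self, ico2, rng):
        parc = synth_parcellation(ico2, 2, rng)
        ind = (parc.labels[:, None] == parc.labels[None, :]).astype(float)
        g = gradient_matrix(0.9 * ind + 0.1, ico2)
        border = {
            v
            for v in range(162)
            if any(parc.labels[u] != parc.labels[v] for u in ico2.neighbor_lists[v])
        }
        hits = sum(int(np.nanargmax(row)) in border for row in g.matrix)
        assert hits == 162  # every seed's gradient peaks on the block border

    def test_shape_preserved_and_nan_rows_propagate(self, ico2_wall, rng):
        rsfc2 = rng.random((162, 162))
        rsfc2 = (rsfc2 + rsfc2.T) / 2
        rsfc2[3] = np.nan
        rsfc2[:, 3] = np.nan
        g = gradient_matrix(rsfc2, ico2_wall)
        assert g.matrix.shape == (162, 162)
        assert np.all(np.isnan(g.matrix[3]))


class TestBoundaryMap:
    def test_monotone_bowl_has_no_boundary(self, ico2):
        d = geodesic_sphere_distance(
            ico2.sphere_coords, ico2.sphere_coords[0][None, :], 100.0
        )
        b = watershed_boundary_map(ScalarMap(d, ico2), ico2)
        assert np.nansum(b.values) == 0

    def test_two_basins_boundary_separates_them(self, ico2):
        d0 = geodesic_sphere_distance(ico2.sphere_coords, ico2.sphere_coords[0][None, :], 100.0)
        d9 = geodesic_sphere_distance(ico2.sphere_coords, ico2.sphere_coords[9][None, :], 100.0)
        vals = np.minimum(d0, d9)
        b = watershed_boundary_map(ScalarMap(vals, ico2), ico2)
        assert np.nansum(b.values) > 0
        # boundary lies on the equidistant ridge
        ridge = np.abs(d0 - d9) < 1.1 * ico2.mean_edge_length
        assert np.all(ridge[b.values == 1])

    def test_constant_map_yields_empty_boundary(self, ico2_wall):
        b = watershed_boundary_map(ScalarMap(np.ones(162), ico2_wall), ico2_wall)
        assert np.nansum(b.values) == 0

    def test_all_undefined_raises(self, ico2_wall):
        with pytest.raises(ValueError):
            watershed_boundary_map(ScalarMap(np.full(162, np.nan), ico2_wall), ico2_wall)


class TestLocalGradientMap:
    def test_identical_maps_average_to_themselves(self, ico2, rng):
        b = (rng.random(162) < 0.3).astype(float)
        out = local_gradient_map([ScalarMap(b, ico2)] * 4, ico2)
        np.testing.assert_array_equal(out.values, b)
        assert out.n_boundary_maps == 4

    def test_single_disagreement_gives_half(self, ico2):
        a = np.zeros(162)
        b = np.zeros(162)
        b[10] = 1.0
        out = local_gradient_map([ScalarMap(a, ico2), ScalarMap(b, ico2)], ico2)
        assert out.values[10] == 0.5
        assert np.nanmin(out.values) >= 0 and np.nanmax(out.values) <= 1

    def test_permutation_invariance(self, ico2, rng):
        maps = [ScalarMap((rng.random(162) < 0.3).astype(float), ico2) for _ in range(5)]
        a = local_gradient_map(maps, ico2).values
        b = local_gradient_map(maps[::-1], ico2).values
        np.testing.assert_array_equal(a, b)

    def test_nonbinary_input_rejected(self, ico2):
        with pytest.raises(ValueError):
            local_gradient_map([ScalarMap(np.full(162, 0.5), ico2)], ico2)
        with pytest.raises(ValueError):
            local_gradient_map([], ico2)


class TestCombineMaps:
    def test_single_map_per_level_is_identity(self, ico2, rng):
        m = lgm(rng.random(162), ico2)
        out = combine_maps([m], ["s1"])
        np.testing.assert_array_equal(out["s1"].values, m.values)

    def test_hierarchical_mean_differs_from_pooled(self, ico2):
        a = lgm(np.full(162, 0.2), ico2)
        b = lgm(np.full(162, 0.4), ico2)
        c = lgm(np.full(162, 0.9), ico2)
        sessions = combine_maps([a, b, c], ["s1", "s1", "s2"])
        visit = combine_maps(list(sessions.values()), ["v", "v"])["v"]
        assert np.allclose(visit.values[0], (0.3 + 0.9) / 2)  # 0.6, not pooled 0.5
        assert not np.isclose(visit.values[0], np.mean([0.2, 0.4, 0.9]))

    def test_age_independent_map_of_equal_groups(self, ico2, rng):
        m = rng.random(162)
        out = age_independent_map([lgm(m, ico2) for _ in range(6)])
        np.testing.assert_allclose(out.values, m, atol=1e-15)
        assert out.group_label == "age-independent"

    def test_missing_group_key_raises(self, ico2, rng):
        m = lgm(rng.random(162), ico2)
        with pytest.raises(ValueError):
            combine_maps([m], [None])


class TestBinarizeAndConsistency:
    def test_top_fraction_counts_and_ties(self, ico2):
        vals = np.zeros(162)
        vals[:10] = np.arange(10, 0, -1)  # 10 distinct positive values
        m = ScalarMap(vals, ico2)
        out = binarize_top(m, 10 / 162 * 0.25)  # top 25% of a 10-value support
        # ceil(0.25*162*10/162)=ceil(2.5)=3 -> top 3 vertices of the support
        assert np.nansum(out.values) == 3
        assert np.all(out.values[:3] == 1)

    def test_frac_one_marks_all_defined(self, ico2_wall, rng):
        m = ScalarMap(rng.random(162), ico2_wall)
        out = binarize_top(m, 1.0)
        assert np.nansum(out.values) == ico2_wall.cortex_mask.sum()

    def test_deterministic(self, ico2, rng):
        m = ScalarMap(rng.random(162), ico2)
        a = binarize_top(m, 0.25).values
        b = binarize_top(m, 0.25).values
        np.testing.assert_array_equal(a, b)

    def test_consistency_of_identical_maps(self, ico2, rng):
        m = lgm(rng.random(162), ico2)
        out = overlap_consistency([m] * 6, top_frac=0.25)
        top = binarize_top(m, 0.25).values == 1
        assert np.all(out.values[top] == 6)
        assert set(np.unique(out.values[np.isfinite(out.values)])) <= {0.0, 6.0}

    def test_disjoint_top_sets_stay_binary(self, ico2):
        a = np.zeros(162)
        b = np.zeros(162)
        a[:50] = 1 + np.arange(50)   # ceil(0.25 * 162) = 41 < 50, so the
        b[50:100] = 1 + np.arange(50)  # top sets stay inside disjoint supports
        out = overlap_consistency([lgm(a, ico2), lgm(b, ico2)], top_frac=0.25)
        assert set(np.unique(out.values)) <= {0.0, 1.0}
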