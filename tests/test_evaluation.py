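import numpy as np
import pytest

from gradparc.evaluation import (
    DEFAULT_N_NULLS,
    binarize_top,
    dice,
    generate_null_parcellations,
    hausdorff_spherical,
    null_comparison,
    null_parcel_metrics,
    parcel_homogeneity,
    parcel_variance,
    split_half_reproducibility,
    variability_between,
)
from gradparc.gradient import LocalGradientMap
from gradparc.mesh import ScalarMap
from gradparc.parcellation import Parcellation
from gradparc.synthetic import synth_parcellation

from _oracles import oracle_hausdorff
from helpers import connected_parcellation


class TestDice:
    def test_self_overlap_is_one(self, ico2, rng):
        a = ScalarMap((rng.random(162) < 0.3).astype(float), ico2)
        assert dice(a, a) == 1.0

    def test_disjoint_sets_zero_and_symmetry(self):
        a = np.zeros(20)
        b = np.zeros(20)
        a[:5] = 1
        b[10:14] = 1
        assert dice(a, b) == 0.0
        assert dice(a, b) == dice(b, a)

    def test_partial_overlap(self):
        a = np.zeros(30)
        b = np.zeros(30)
        a[:4] = 1
        b[1:7] = 1  # |A|=4, |B|=6, |A n B|=3
        assert np.isclose(dice(a, b), 0.6)

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros(9), np.zeros(9)) == 1.0


class TestSplitHalfReproducibility:
    def test_identical_subjects_are_perfectly_reproducible(self, ico2, rng):
        m = LocalGradientMap(rng.random(162), ico2)
        mean, sd, samples = split_half_reproducibility([m] * 6, n_rep=20, rng=0)
        assert mean == 1.0 and sd == 0.0

    def test_independent_noise_maps_near_chance_overlap(self, ico2):
        # random independent rankings: expected dice of top-f sets is ~f
        gen = np.random.default_rng(42)
        maps = [LocalGradientMap(gen.random(162), ico2) for _ in range(16)]
        mean, sd, _ = split_half_reproducibility(maps, n_rep=200, frac=0.25, rng=1)
        assert abs(mean - 0.25) < 0.08

    def test_seeded_and_needs_two_subjects(self, ico2, rng):
        maps = [LocalGradientMap(rng.random(162), ico2) for _ in range(4)]
        a = split_half_reproducibility(maps, n_rep=10, rng=7)[2]
        b = split_half_reproducibility(maps, n_rep=10, rng=7)[2]
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            split_half_reproducibility(maps[:1])


class TestHomogeneity:
    def test_rank_one_profiles_are_fully_homogeneous(self, ico2):
        parc = connected_parcellation(ico2, [6])
        profiles = np.outer(np.ones(162), np.array([1.0, 2.0, 3.0]))
        assert np.isclose(parcel_homogeneity(parc, profiles)[0], 100.0)

    def test_matches_eigendecomposition_oracle(self, ico2, rng):
        parc = connected_parcellation(ico2, [3])
        members = parc.parcel_vertices(1)
        profiles = np.zeros((162, 4))
        profiles[members] = rng.standard_normal((3, 4))
        got = parcel_homogeneity(parc, profiles)[0]
        scatter = profiles[members].T @ profiles[members]  # uncentered
        ev = np.linalg.eigvalsh(scatter)
        assert np.isclose(got, 100 * ev[-1] / ev.sum())

    def test_isotropic_noise_approaches_one_over_d(self, ico2):
        gen = np.random.default_rng(5)
        parc = connected_parcellation(ico2, [150])
        d = 4
        profiles = gen.standard_normal((162, d))
        got = parcel_homogeneity(parc, profiles)[0]
        assert abs(got - 100 / d) < 12

    def test_single_vertex_parcel_convention(self, ico2, rng):
        labels = np.zeros(162, dtype=int)
        labels[0] = 1
        parc = Parcellation(labels, ico2)
        assert parcel_homogeneity(parc, rng.random((162, 5)))[0] == 100.0

    def test_invariant_to_vertex_order(self, ico2, rng):
        parc = connected_parcellation(ico2, [8])
        members = parc.parcel_vertices(1)
        profiles = rng.standard_normal((162, 6))
        a = parcel_homogeneity(parc, profiles)[0]
        shuffled = profiles.copy()
        shuffled[members] = profiles[members][::-1]
        assert np.isclose(a, parcel_homogeneity(parc, shuffled)[0])


class TestVariance:
    def test_identical_columns_have_zero_variability(self, ico2):
        parc = connected_parcellation(ico2, [5])
        profiles = np.tile(np.array([0.3, 0.7, 0.1]), (162, 1))
        per, mean = parcel_variance(parc, profiles)
        assert per[0] == 0.0 and mean == 0.0

    def test_two_by_two_hand_computation(self, ico2):
        parc = connected_parcellation(ico2, [2])
        v1, v2 = parc.parcel_vertices(1)
        profiles = np.zeros((162, 2))
        profiles[v1] = [1.0, 3.0]
        profiles[v2] = [2.0, 7.0]
        per, _ = parcel_variance(parc, profiles)
        assert np.isclose(per[0], 0.5 + 2.0)  # row stds (ddof=0): 0.5 and 2

    def test_shift_invariance(self, ico2, rng):
        parc = connected_parcellation(ico2, [7])
        profiles = rng.standard_normal((162, 5))
        a = parcel_variance(parc, profiles)[0][0]
        b = parcel_variance(parc, profiles + 11.0)[0][0]
        assert np.isclose(a, b)

    def test_single_vertex_parcel_is_zero(self, ico2, rng):
        labels = np.zeros(162, dtype=int)
        labels[0] = 1
        parc = Parcellation(labels, ico2)
        assert parcel_variance(parc, rng.random((162, 4)))[0][0] == 0.0


class TestRotationNulls:
    def test_resampling_roughly_preserves_parcel_sizes(self, ico2_wall, rng):
        parc = synth_parcellation(ico2_wall, 5, rng)
        ens = generate_null_parcellations(parc, ico2_wall, n=20, rng=1)
        orig = np.bincount(parc.labels, minlength=6)[1:]
        for i in range(ens.n):
            sizes = np.bincount(ens.labels[i], minlength=6)[1:]
            kept = ~ens.wall_flags[i]
            assert np.all(np.abs(sizes[kept] - orig[kept]) <= 0.35 * orig[kept] + 3)

    def test_seeded_ensembles_regenerate_identically(self, ico2_wall, rng):
        parc = synth_parcellation(ico2_wall, 5, rng)
        a = generate_null_parcellations(parc, ico2_wall, n=5, rng=9)
        b = generate_null_parcellations(parc, ico2_wall, n=5, rng=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.rotations, b.rotations)

    def test_default_ensemble_size_is_1000(self):
        assert DEFAULT_N_NULLS == 1000

    def test_n_below_one_raises(self, ico2_wall, rng):
        parc = synth_parcellation(ico2_wall, 4, rng)
        with pytest.raises(ValueError):
            generate_null_parcellations(parc, ico2_wall, n=0, rng=0)

    def test_wall_flagged_parcels_excluded_from_metrics(self, ico2_wall, rng):
        parc = synth_parcellation(ico2_wall, 5, rng)
        ens = generate_null_parcellations(parc, ico2_wall, n=30, rng=2)

        def metric(labels):
            out = np.full(parc.n_parcels, np.nan)
            for pid in range(1, parc.n_parcels + 1):
                if np.any(labels == pid):
                    out[pid - 1] = float(np.sum(labels == pid))
            return out

        per_null, per_parcel = null_parcel_metrics(ens, metric)
        assert np.all(np.isnan(per_null[ens.wall_flags]))
        assert np.all(np.isfinite(per_parcel))


class TestNullComparison:
    def test_rank_formula_extremes(self):
        nulls = np.arange(999, dtype=float)
        assert null_comparison(1e9, nulls, "greater") == 1 / 1000
        assert null_comparison(-1e9, nulls, "less") == 1 / 1000

    def test_median_gives_half(self):
        nulls = np.arange(101, dtype=float)
        p = null_comparison(50.0, nulls, "greater")
        assert abs(p - 0.5) < 0.01

    def test_direction_flips_tail(self):
        nulls = np.array([1.0, 2.0, 3.0])
        assert null_comparison(2.5, nulls, "greater") < null_comparison(2.5, nulls, "less")


class TestHausdorff:
    def test_identity_and_singletons(self, ico2):
        assert hausdorff_spherical({3, 5}, {3, 5}, ico2) == 0.0
        from gradparc.mesh import geodesic_sphere_distance

        d = geodesic_sphere_distance(ico2.sphere_coords[0], ico2.sphere_coords[1], 100.0)
        assert np.isclose(hausdorff_spherical({0}, {1}, ico2), d)

    def test_matches_exhaustive_oracle(self, ico2, rng):
        for _ in range(10):
            a = rng.choice(162, 3, replace=False)
            b = rng.choice(162, 4, replace=False)
            got = hausdorff_spherical(set(a.tolist()), set(b.tolist()), ico2)
            exp = oracle_hausdorff(
                ico2.sphere_coords[a], ico2.sphere_coords[b], 100.0
            )
            assert np.isclose(got, exp)
            assert np.isclose(
                got, hausdorff_spherical(set(b.tolist()), set(a.tolist()), ico2)
            )

    def test_empty_set_raises(self, ico2):
        with pytest.raises(ValueError):
            hausdorff_spherical(set(), {1}, ico2)


class TestVariability:
    def test_self_variability_is_zero(self, ico2_wall, rng):
        g = LocalGradientMap(rng.random(162), ico2_wall)
        v = variability_between(g, g, ico2_wall, ring=3)
        assert np.nanmax(v.values) < 1e-12

    def test_anticorrelated_variability_is_one(self, ico2_wall, rng):
        g1 = LocalGradientMap(rng.random(162), ico2_wall)
        g2 = LocalGradientMap(1.0 - g1.values, ico2_wall)
        v = variability_between(g1, g2, ico2_wall, ring=3)
        assert np.nanmin(v.values) > 1.0 - 1e-12

    def test_matches_patch_pearson_by_hand(self, ico2, rng):
        g1 = LocalGradientMap(rng.random(162), ico2)
        g2 = LocalGradientMap(rng.random(162), ico2)
        v = variability_between(g1, g2, ico2, ring=2)
        from gradparc.mesh import k_ring_neighborhood

        for vertex in (0, 50, 101):
            patch = sorted(k_ring_neighborhood(ico2, vertex, 2))
            r = np.corrcoef(g1.values[patch], g2.values[patch])[0, 1]
            assert np.isclose(v.values[vertex], 0.5 * (1 - r))

    def test_constant_patch_flagged_undefined(self, ico2):
        g1 = LocalGradientMap(np.ones(162), ico2)
        g2 = LocalGradientMap(np.linspace(0, 1, 162), ico2)
        v = variability_between(g1, g2, ico2, ring=2)
        assert np.all(np.isnan(v.values))
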