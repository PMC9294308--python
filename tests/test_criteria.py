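import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcbc
from dcbc.exceptions import EvaluationError, MaskedVertexError, ParameterError

import oracles


class TestFunctionalProfiles:
    def test_requires_two_conditions(self):
        with pytest.raises(ParameterError):
            dcbc.FunctionalProfiles(np.ones((5, 1)))

    def test_nonfinite_and_flat_rows_masked(self):
        values = np.random.default_rng(0).standard_normal((4, 3))
        values[1, 0] = np.nan
        values[2] = 7.0  # zero variance across conditions
        p = dcbc.FunctionalProfiles(values)
        assert list(p.valid_mask) == [True, False, False, True]


class TestPairwiseCorrelation:
    def test_identical_profiles(self):
        p = dcbc.FunctionalProfiles(np.array([[1.0, 2, 3], [1, 2, 3]]))
        assert dcbc.pairwise_correlation(p, 0, 1) == pytest.approx(1.0)

    def test_negated_profile(self):
        p = dcbc.FunctionalProfiles(np.array([[1.0, 2, 3], [-1, -2, -3]]))
        assert dcbc.pairwise_correlation(p, 0, 1) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        p = dcbc.FunctionalProfiles(np.array([[1.0, 2, 3], [1, 3, 2]]))
        assert dcbc.pairwise_correlation(p, 0, 1) == pytest.approx(0.5)

    def test_masked_vertex_raises(self):
        values = np.array([[1.0, 2, 3], [5.0, 5, 5]])
        p = dcbc.FunctionalProfiles(values)
        with pytest.raises(MaskedVertexError):
            dcbc.pairwise_correlation(p, 0, 1)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((10, 7))
        p = dcbc.FunctionalProfiles(values)
        for i in range(10):
            for j in range(i + 1, 10):
                assert dcbc.pairwise_correlation(p, i, j) == pytest.approx(
                    oracles.pearson(values[i], values[j]), abs=1e-12
                )


class TestBinning:
    def test_edge_distances_fall_in_lower_bin(self):
        spec = dcbc.BinSpec(bin_width_mm=1.0, max_dist_mm=5.0)
        np.testing.assert_array_equal(
            spec.bin_index(np.array([0.5, 1.0, 1.2])), [0, 0, 1]
        )

    def test_counts_match_exhaustive_enumeration(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        spec = dcbc.BinSpec(bin_width_mm=10.0, max_dist_mm=100.0)
        stats = dcbc.classify_and_bin_pairs(parc, dist, spec, profiles.valid_mask)
        n_w, n_b = oracles.brute_pair_counts(
            parc.labels, dist, 10.0, 100.0, profiles.valid_mask
        )
        np.testing.assert_array_equal(stats.n_within, n_w)
        np.testing.assert_array_equal(stats.n_between, n_b)
        # each qualifying pair lands in exactly one bin
        assert stats.n_within.sum() + stats.n_between.sum() == n_w.sum() + n_b.sum()

    def test_unassigned_vertices_excluded(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        spec = dcbc.BinSpec(bin_width_mm=10.0, max_dist_mm=100.0)
        all_on = dcbc.classify_and_bin_pairs(parc, dist, spec, None)
        labels = parc.labels.copy()
        labels[labels == 3] = 0
        fewer = dcbc.classify_and_bin_pairs(
            dcbc.Parcellation(labels=labels), dist, spec, None
        )
        assert fewer.n_within.sum() < all_on.n_within.sum()
        assert fewer.n_between.sum() < all_on.n_between.sum()

    def test_max_dist_beyond_cutoff_rejected(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        with pytest.raises(ParameterError):
            dcbc.classify_and_bin_pairs(
                parc, dist, dcbc.BinSpec(1.0, dist.cutoff_mm + 1), None
            )


class TestWeights:
    def test_precision_weighting_example(self):
        w = dcbc.compute_weights(np.array([2, 8]), np.array([2, 8]))
        np.testing.assert_allclose(w, [0.2, 0.8])

    def test_equal_counts_give_uniform_weights(self):
        w = dcbc.compute_weights(np.array([5, 5, 5]), np.array([7, 7, 7]))
        np.testing.assert_allclose(w, [1 / 3] * 3)

    def test_bins_missing_a_pair_kind_are_excluded(self):
        w = dcbc.compute_weights(np.array([4, 0]), np.array([4, 5]))
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_no_usable_bin_raises(self):
        with pytest.raises(EvaluationError):
            dcbc.compute_weights(np.array([4, 0]), np.array([0, 5]))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        n_w = rng.integers(0, 50, 20)
        n_b = rng.integers(0, 50, 20)
        w = dcbc.compute_weights(n_w, n_b)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestDCBC:
    def test_matches_brute_force_on_toy_fixture(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        spec = dcbc.BinSpec(bin_width_mm=15.0, max_dist_mm=105.0)
        res = dcbc.compute_dcbc(profiles, parc, dist, spec)
        exp_w, exp_u = oracles.brute_dcbc(
            profiles.values, parc.labels, dist, 15.0, 105.0, profiles.valid_mask
        )
        assert res.dcbc == pytest.approx(exp_w, abs=1e-10)
        assert res.dcbc_unweighted == pytest.approx(exp_u, abs=1e-10)
        # invariants of the result object
        inc = res.included_bins
        assert res.weights[inc].sum() == pytest.approx(1.0, abs=1e-12)
        assert res.dcbc == pytest.approx(
            float(np.sum(res.weights[inc] * res.d_i[inc])), abs=1e-12
        )

    def test_shared_profile_gives_zero(self, toy_eval):
        mesh, dist, parc, _ = toy_eval
        base = np.array([1.0, -2.0, 0.5, 3.0, 1.5, -1.0])
        profiles = dcbc.FunctionalProfiles(np.tile(base, (mesh.n_vertices, 1)))
        res = dcbc.compute_dcbc(profiles, parc, dist, dcbc.BinSpec(15.0, 105.0))
        assert res.dcbc == pytest.approx(0.0, abs=1e-12)
        assert res.dcbc_unweighted == pytest.approx(0.0, abs=1e-12)

    def test_single_parcel_is_an_error(self, toy_eval):
        mesh, dist, _, profiles = toy_eval
        parc = dcbc.Parcellation(labels=np.ones(mesh.n_vertices, dtype=int))
        with pytest.raises(EvaluationError):
            dcbc.compute_dcbc(profiles, parc, dist, dcbc.BinSpec(15.0, 105.0))


class TestUnbinnedACD:
    def test_equals_single_bin_difference(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        acd = dcbc.unbinned_acd(profiles, parc, dist, 105.0)
        res = dcbc.compute_dcbc(profiles, parc, dist, dcbc.BinSpec(105.0, 105.0))
        assert res.weights[0] == pytest.approx(1.0)
        assert acd == pytest.approx(res.dcbc, abs=1e-12)

    def test_matches_brute_force(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        exp = oracles.brute_acd(
            profiles.values, parc.labels, dist, 105.0, profiles.valid_mask
        )
        assert dcbc.unbinned_acd(profiles, parc, dist, 105.0) == pytest.approx(
            exp, abs=1e-10
        )

    def test_shared_profile_gives_zero(self, toy_eval):
        mesh, dist, parc, _ = toy_eval
        profiles = dcbc.FunctionalProfiles(
            np.tile([2.0, 0.0, 1.0, -1.0], (mesh.n_vertices, 1))
        )
        assert dcbc.unbinned_acd(profiles, parc, dist, 105.0) == pytest.approx(0.0)


class TestHomogeneity:
    def test_identical_profiles_give_one(self, toy_eval):
        mesh, _, parc, _ = toy_eval
        profiles = dcbc.FunctionalProfiles(
            np.tile([1.0, 2.0, 4.0], (mesh.n_vertices, 1))
        )
        assert dcbc.compute_homogeneity(profiles, parc) == pytest.approx(1.0)

    def test_matches_brute_force(self, toy_eval):
        mesh, _, parc, profiles = toy_eval
        exp = oracles.brute_homogeneity(
            profiles.values, parc.labels, profiles.valid_mask
        )
        assert dcbc.compute_homogeneity(profiles, parc) == pytest.approx(exp, abs=1e-10)

    def test_unweighted_average_across_parcels(self):
        # two parcels of different sizes: the global value is the plain mean
        # of the two per-parcel means, not the pair-count-weighted mean
        rng = np.random.default_rng(5)
        values = rng.standard_normal((8, 5))
        labels = np.array([1, 1, 2, 2, 2, 2, 2, 2])
        profiles = dcbc.FunctionalProfiles(values)
        per_parcel = [
            oracles.brute_homogeneity(values, np.where(labels == k, 1, 0), [True] * 8)
            for k in (1, 2)
        ]
        got = dcbc.compute_homogeneity(profiles, dcbc.Parcellation(labels=labels))
        assert got == pytest.approx(np.mean(per_parcel), abs=1e-10)


class TestSilhouette:
    def test_perfect_separation_gives_one(self, sphere2):
        # same profile within each hemifield, orthogonal across them
        labels = np.where(sphere2.vertices[:, 2] >= 0, 1, 2)
        values = np.where(
            labels[:, None] == 1, [1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]
        )
        profiles = dcbc.FunctionalProfiles(values)
        parc = dcbc.Parcellation(labels=labels)
        adj = dcbc.parcel_adjacency(parc, sphere2)
        s_i, mean = dcbc.compute_silhouette(profiles, parc, adj)
        assert mean == pytest.approx(1.0)

    def test_identical_everything_gives_zero(self, sphere2):
        labels = np.where(sphere2.vertices[:, 2] >= 0, 1, 2)
        profiles = dcbc.FunctionalProfiles(
            np.tile([3.0, 1.0, 2.0], (sphere2.n_vertices, 1))
        )
        parc = dcbc.Parcellation(labels=labels)
        adj = dcbc.parcel_adjacency(parc, sphere2)
        s_i, mean = dcbc.compute_silhouette(profiles, parc, adj)
        assert mean == pytest.approx(0.0, abs=1e-12)  # w_i == b_i everywhere

    def test_matches_brute_force_and_range(self, toy_eval):
        mesh, _, parc, profiles = toy_eval
        adj = dcbc.parcel_adjacency(parc, mesh)
        s_i, mean = dcbc.compute_silhouette(profiles, parc, adj)
        neighbors = {k: set(v) for k, v in adj.neighbors.items()}
        exp = oracles.brute_silhouette(
            profiles.values, parc.labels, neighbors, profiles.valid_mask
        )
        assert mean == pytest.approx(exp, abs=1e-10)
        finite = s_i[np.isfinite(s_i)]
        assert ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all()


class TestGroupSummary:
    def test_all_zero_values(self):
        s = dcbc.group_summary([0.0, 0.0, 0.0])
        assert s.mean == 0.0 and s.t == 0.0

    def test_degenerate_constant_sample(self):
        s = dcbc.group_summary([1.0, 1.0, 1.0, 1.0])
        assert s.se == 0.0 and np.isinf(s.t) and s.t > 0 and s.p == 0.0

    def test_hand_computed_se(self):
        s = dcbc.group_summary([0.1, 0.2, 0.3])
        assert s.mean == pytest.approx(0.2)
        assert s.se == pytest.approx(0.1 / np.sqrt(3), abs=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ParameterError):
            dcbc.group_summary([0.5])


class TestEvaluateSubject:
    def test_hemisphere_average(self, toy_eval):
        mesh, dist, parc, profiles = toy_eval
        spec = dcbc.BinSpec(15.0, 105.0)
        one = dcbc.compute_dcbc(profiles, parc, dist, spec).dcbc
        hemi = (profiles, parc, dist)
        assert dcbc.evaluate_subject([hemi, hemi], spec) == pytest.approx(one)
        assert dcbc.evaluate_subject([hemi], spec) == pytest.approx(one)
        # distinct hemispheres: plain mean of the two values
        rng = np.random.default_rng(9)
        other = dcbc.FunctionalProfiles(
            profiles.values + 0.5 * rng.standard_normal(profiles.values.shape)
        )
        two = dcbc.compute_dcbc(other, parc, dist, spec).dcbc
        got = dcbc.evaluate_subject([hemi, (other, parc, dist)], spec)
        assert got == pytest.approx((one + two) / 2)


class TestPearsonInvariance:
    """All criteria depend on profiles only through Pearson correlations."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
        perm_seed=st.integers(0, 2**16),
    )
    def test_affine_rescaling_and_condition_order(self, toy_eval, scale, offset, perm_seed):
        mesh, dist, parc, profiles = toy_eval
        spec = dcbc.BinSpec(15.0, 105.0)
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(profiles.values.shape[1])
        per_vertex = scale * (1 + rng.uniform(0, 1, (profiles.n_vertices, 1)))
        transformed = dcbc.FunctionalProfiles(
            per_vertex * profiles.values[:, perm] + offset
        )
        adj = dcbc.parcel_adjacency(parc, mesh)
        for f in (
            lambda p: dcbc.compute_dcbc(p, parc, dist, spec).dcbc,
            lambda p: dcbc.unbinned_acd(p, parc, dist, 105.0),
            lambda p: dcbc.compute_homogeneity(p, parc),
            lambda p: dcbc.compute_silhouette(p, parc, adj)[1],
        ):
            assert f(transformed) == pytest.approx(f(profiles), abs=1e-9)
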