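"""k-means, randomized-reference k selection, UPGMA reclustering, subclusters."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from xplatclust import (
    DEFAULT_K_GRID,
    SimConfig,
    combine_platforms,
    kmeans_cluster,
    log2_fold_change,
    recluster_centroids,
    select_k,
    simulate_dataset,
    size_factors,
    subcluster,
    within_cluster_variance,
)
from xplatclust.cluster import linkage_to_newick, per_cluster_variance


def frame(rows, prefix="f"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(rows.shape[0])],
        columns=[f"{prefix}{j}" for j in range(rows.shape[1])],
    )


def combined_profiles(cfg):
    array_em, counts_em, _, truth = simulate_dataset(cfg)
    sf = size_factors(counts_em)
    fa = log2_fold_change(array_em, 0.0)
    fc = log2_fold_change(counts_em, 1.0, size_factors=sf)
    return combine_platforms(fa, fc).values, truth


class TestKMeans:
    def test_duplicated_points_reach_zero_variance(self):
        distinct = np.array([[0.0, 0.0], [5.0, 5.0], [-4.0, 2.0]])
        X = frame(np.repeat(distinct, 4, axis=0))
        model = kmeans_cluster(X, k=3, seed=0, n_init=10)
        assert model.within_cluster_variance == pytest.approx(0.0, abs=1e-12)
        labels = model.assignment.to_numpy()
        for block in (labels[:4], labels[4:8], labels[8:]):
            assert len(set(block)) == 1

    def test_k1_centroid_is_grand_mean(self):
        X = frame([[1.0, 2.0], [3.0, 6.0], [5.0, 1.0]])
        model = kmeans_cluster(X, k=1, seed=0)
        np.testing.assert_allclose(
            model.centroids.iloc[0].to_numpy(), X.to_numpy().mean(axis=0)
        )

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(3)
        X = frame(rng.normal(size=(40, 5)))
        model = kmeans_cluster(X, k=4, seed=1)
        for cid in model.centroids.index:
            members = model.members(cid)
            np.testing.assert_allclose(
                model.centroids.loc[cid].to_numpy(),
                X.loc[members].to_numpy().mean(axis=0),
                atol=1e-12,
            )

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(frame([[0.0], [1.0]]), k=3, seed=0)

    def test_recovers_planted_clusters(self):
        cfg = SimConfig(
            n_clusters=8, genes_per_cluster=50, profile_noise_sd=0.2,
            replication_fraction=1.0, seed=13,
        )
        profiles, truth = combined_profiles(cfg)
        model = kmeans_cluster(profiles, k=8, seed=5, n_init=25)
        ari = adjusted_rand_score(
            truth.assignment.loc[model.assignment.index], model.assignment
        )
        assert ari >= 0.9

    def test_matches_exhaustive_optimum_on_tiny_instance(self):
        # oracle: enumerate every assignment of 7 points into <= 3 groups
        rng = np.random.default_rng(8)
        X = frame(rng.normal(size=(7, 2)))
        arr = X.to_numpy()
        k = 3

        def total_ss(labels):
            ss = 0.0
            for c in set(labels):
                pts = arr[np.array(labels) == c]
                ss += ((pts - pts.mean(axis=0)) ** 2).sum()
            return ss

        best = min(
            total_ss(labels)
            for labels in itertools.product(range(k), repeat=len(arr))
            if len(set(labels)) == k
        )
        model = kmeans_cluster(X, k=k, seed=0, n_init=50)
        achieved = sum(
            ((arr[model.assignment.to_numpy() == c]
              - model.centroids.loc[c].to_numpy()) ** 2).sum()
            for c in model.centroids.index
        )
        assert achieved == pytest.approx(best, rel=1e-9)

    def test_more_inits_never_worse(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(size=(60, 6)))
        wcv = [
            kmeans_cluster(X, k=6, seed=11, n_init=n).within_cluster_variance
            for n in (1, 5, 25)
        ]
        assert wcv[0] >= wcv[1] >= wcv[2]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = frame(rng.normal(size=(30, 4)))
        m1 = kmeans_cluster(X, k=3, seed=9)
        m2 = kmeans_cluster(X, k=3, seed=9)
        pd.testing.assert_series_equal(m1.assignment, m2.assignment)


class TestWithinClusterVariance:
    def test_points_at_centroids_give_zero(self):
        X = frame([[1.0], [2.0]])
        assignment = pd.Series([1, 2], index=X.index)
        centroids = pd.DataFrame([[1.0], [2.0]], index=[1, 2], columns=X.columns)
        assert within_cluster_variance(X, assignment, centroids) == 0.0

    def test_two_point_cluster_arithmetic(self):
        # cluster {0, 2} with centroid 1: mean squared distance is 1
        X = frame([[0.0], [2.0]])
        assignment = pd.Series([1, 1], index=X.index)
        centroids = pd.DataFrame([[1.0]], index=[1], columns=X.columns)
        assert within_cluster_variance(X, assignment, centroids) == pytest.approx(1.0)

    def test_duplicating_genes_leaves_value_unchanged(self):
        rng = np.random.default_rng(1)
        X = frame(rng.normal(size=(10, 3)))
        assignment = pd.Series(rng.integers(1, 3, size=10), index=X.index)
        centroids = pd.DataFrame(
            [X[assignment == c].mean() for c in (1, 2)], index=[1, 2]
        )
        v1 = within_cluster_variance(X, assignment, centroids)
        X2 = pd.concat([X, X.set_index(X.index + "_dup")])
        a2 = pd.concat([assignment, assignment.set_axis(X.index + "_dup")])
        v2 = within_cluster_variance(X2, a2, centroids)
        assert v2 == pytest.approx(v1)

    def test_empty_cluster_errors(self):
        X = frame([[0.0]])
        assignment = pd.Series([1], index=X.index)
        centroids = pd.DataFrame([[0.0], [9.0]], index=[1, 2], columns=X.columns)
        with pytest.raises(ValueError, match="no members"):
            within_cluster_variance(X, assignment, centroids)


class TestSelectK:
    def test_default_grid_matches_convention(self):
        assert DEFAULT_K_GRID == (5, 10, 15, 20, 25, 30, 35, 40, 45, 50,
                                  60, 70, 80, 90, 100)

    def test_structured_data_crosses_below_randomized(self):
        cfg = SimConfig(
            n_clusters=10, genes_per_cluster=30, profile_noise_sd=0.15,
            amplitude_range=(1.5, 3.0), seed=21,
        )
        profiles, _ = combined_profiles(cfg)
        trace = select_k(
            profiles, k_grid=tuple(range(5, 51, 5)), n_randomizations=3,
            seed=2, n_init=5,
        )
        assert trace.chosen_k <= 50
        i = trace.k_grid.index(trace.chosen_k)
        assert trace.actual_variance[i] < trace.randomized_variance[i]
        assert not trace.fell_through

    def test_iid_noise_falls_through_with_warning(self):
        rng = np.random.default_rng(6)
        profiles = frame(rng.normal(size=(200, 10)))
        with pytest.warns(UserWarning, match="falling through"):
            trace = select_k(
                profiles, k_grid=(5, 10, 15), n_randomizations=3, seed=3, n_init=5
            )
        assert trace.fell_through
        assert trace.chosen_k == 15

    def test_oversized_k_skipped_with_warning(self):
        rng = np.random.default_rng(7)
        profiles = frame(rng.normal(size=(12, 4)))
        with pytest.warns(UserWarning, match="skipped"):
            trace = select_k(profiles, k_grid=(5, 50), n_randomizations=2, seed=0,
                             n_init=3)
        assert trace.skipped == [50]
        assert trace.k_grid == [5]

    def test_randomization_preserves_column_multisets(self):
        from xplatclust.cluster import _randomize_columns

        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        R = _randomize_columns(X, rng)
        for j in range(X.shape[1]):
            np.testing.assert_array_equal(np.sort(R[:, j]), np.sort(X[:, j]))
        assert not np.array_equal(R, X)


class TestReclusterCentroids:
    def test_identical_pair_merges_first_at_zero(self):
        centroids = pd.DataFrame(
            [[0.0, 0.0], [3.0, 3.0], [0.0, 0.0]], index=[1, 2, 3]
        )
        Z, order = recluster_centroids(centroids)
        assert Z[0, 2] == pytest.approx(0.0)
        merged = {int(Z[0, 0]), int(Z[0, 1])}
        assert merged == {0, 2}  # positions of the identical pair

    def test_collinear_upgma_heights_hand_computed(self):
        centroids = pd.DataFrame([[0.0], [1.0], [10.0]], index=[1, 2, 3])
        Z, order = recluster_centroids(centroids)
        assert Z[0, 2] == pytest.approx(1.0)  # {0,1} merge first
        assert Z[1, 2] == pytest.approx(9.5)  # average of 10-0 and 10-1
        assert order in ([1, 2, 3], [3, 1, 2], [2, 1, 3], [3, 2, 1])

    def test_input_order_invariant_topology(self):
        rng = np.random.default_rng(2)
        centroids = pd.DataFrame(rng.normal(size=(5, 4)), index=[1, 2, 3, 4, 5])
        Z1, _ = recluster_centroids(centroids)
        perm = [3, 1, 5, 2, 4]
        Z2, _ = recluster_centroids(centroids.loc[perm])
        # same multiset of merge heights regardless of input order
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_single_centroid_trivial_tree(self):
        centroids = pd.DataFrame([[1.0, 2.0]], index=[7])
        Z, order = recluster_centroids(centroids)
        assert Z.shape == (0, 4)
        assert order == [7]

    def test_newick_renders_all_leaves(self):
        centroids = pd.DataFrame([[0.0], [1.0], [10.0]], index=[1, 2, 3])
        Z, _ = recluster_centroids(centroids)
        nwk = linkage_to_newick(Z, [1, 2, 3])
        assert nwk.endswith(";")
        for leaf in ("1", "2", "3"):
            assert leaf in nwk


class TestSubcluster:
    def test_cut_height_zero_separates_distinct_profiles(self):
        X = frame([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        labels = subcluster(X, cut_height=0.0)
        assert labels.nunique() == 3

    def test_single_subcluster_groups_everything(self):
        X = frame([[0.0], [5.0], [9.0]])
        labels = subcluster(X, n_subclusters=1)
        assert labels.nunique() == 1

    def test_recovers_planted_split(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 0.1, size=(20, 6)) + np.linspace(0, 3, 6)
        b = rng.normal(0.0, 0.1, size=(20, 6)) - np.linspace(0, 3, 6)
        X = frame(np.vstack([a, b]))
        labels = subcluster(X, n_subclusters=2, parent_label=15)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(labels) == {"15.1", "15.2"}

    def test_too_many_subclusters_rejected(self):
        X = frame([[0.0], [1.0]])
        with pytest.raises(ValueError):
            subcluster(X, n_subclusters=5)

    def test_requires_exactly_one_cut_parameter(self):
        X = frame([[0.0], [1.0]])
        with pytest.raises(ValueError, match="exactly one"):
            subcluster(X)
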