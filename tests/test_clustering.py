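import itertools

import numpy as np
import pytest

from ensemblebin.clustering import (
    Binning,
    generate_component_binnings,
    partial_seed_kmeans,
    select_bin_number,
    substream,
    weighted_kmeanspp_init,
    weighted_lloyd,
)
from ensemblebin.features import FeatureSet
from ensemblebin.markers import SeedPlan


def brute_force_best_partition(X, weights, k):
    """Exhaustive minimum weighted inertia over all assignments (tiny n only)."""
    n = X.shape[0]
    best_inertia, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = 0.0
        for j in range(k):
            mask = labels == j
            center = np.average(X[mask], axis=0, weights=weights[mask])
            inertia += np.sum(weights[mask] * np.sum((X[mask] - center) ** 2, axis=1))
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    return best_inertia, best_labels


def is_single_move_local_optimum(X, weights, labels, tol=1e-9):
    """Lloyd-local check: with centers fixed at the weighted cluster means,
    no single-point reassignment lowers inertia (every point already sits
    at its nearest center). This is the fixed point Lloyd guarantees;
    Hartigan-style moves with re-optimized centers can still improve."""
    ks = sorted(set(labels.tolist()))
    centers = np.vstack([
        np.average(X[labels == j], axis=0, weights=weights[labels == j]) for j in ks
    ])
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assigned = np.array([ks.index(l) for l in labels])
    own = d2[np.arange(len(labels)), assigned]
    return bool(np.all(own <= d2.min(axis=1) + tol))


class TestKmeansppInit:
    def test_d2_forces_far_point(self):
        X = np.array([[0.0], [10.0]])
        w = np.ones(2)
        for seed in range(10):
            centers = weighted_kmeanspp_init(X, w, 2, rng=np.random.default_rng(seed))
            assert sorted(centers[:, 0].tolist()) == [0.0, 10.0]

    def test_all_fixed_returns_exact_rows(self):
        X = np.arange(12.0).reshape(4, 3)
        centers = weighted_kmeanspp_init(X, np.ones(4), 2, fixed_centers=[3, 1], rng=None)
        np.testing.assert_array_equal(centers, X[[3, 1]])

    def test_zero_weight_point_never_sampled(self):
        X = np.array([[0.0], [5.0], [10.0]])
        w = np.array([1.0, 0.0, 1.0])
        for seed in range(20):
            centers = weighted_kmeanspp_init(
                X, w, 2, rng=np.random.default_rng(seed)
            )
            assert 5.0 not in centers[:, 0]

    def test_duplicate_points_fallback(self):
        X = np.zeros((4, 2))
        centers = weighted_kmeanspp_init(X, np.ones(4), 3, rng=np.random.default_rng(0))
        assert centers.shape == (3, 2)

    def test_k_exceeds_n_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            weighted_kmeanspp_init(np.zeros((2, 1)), np.ones(2), 3)

    def test_duplicate_fixed_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            weighted_kmeanspp_init(np.zeros((3, 1)), np.ones(3), 2, fixed_centers=[0, 0])


class TestWeightedLloyd:
    def test_two_pair_toy(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        result = weighted_lloyd(X, np.ones(4), np.array([[0.5], [10.5]]))
        assert result.inertia == pytest.approx(1.0)
        np.testing.assert_allclose(sorted(result.centers[:, 0]), [0.5, 10.5])

    def test_weight_equals_duplication(self):
        X = np.array([[0.0], [1.0], [10.0]])
        w = np.array([2.0, 1.0, 1.0])
        X_dup = np.array([[0.0], [0.0], [1.0], [10.0]])
        init = np.array([[0.3], [9.0]])
        r_w = weighted_lloyd(X, w, init)
        r_d = weighted_lloyd(X_dup, np.ones(4), init)
        np.testing.assert_allclose(
            np.sort(r_w.centers, axis=0), np.sort(r_d.centers, axis=0), atol=1e-9
        )

    def test_k1_center_is_weighted_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        w = rng.uniform(0.5, 2.0, size=6)
        result = weighted_lloyd(X, w, X[[0]])
        np.testing.assert_allclose(
            result.centers[0], np.average(X, axis=0, weights=w), atol=1e-6
        )

    def test_inertia_history_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        w = rng.uniform(0.1, 5.0, size=40)
        result = weighted_lloyd(X, w, X[:5].copy())
        history = result.inertia_history
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_nonfinite_rejected(self):
        X = np.array([[0.0], [np.inf]])
        with pytest.raises(ValueError, match="non-finite"):
            weighted_lloyd(X, np.ones(2), X[[0]])

    def test_zero_weight_sum_rejected(self):
        X = np.zeros((3, 1))
        with pytest.raises(ValueError, match="weights"):
            weighted_lloyd(X, np.zeros(3), X[[0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_result_is_local_optimum(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 2))
        w = rng.uniform(0.5, 2.0, size=8)
        init = weighted_kmeanspp_init(X, w, 3, rng=rng)
        result = weighted_lloyd(X, w, init)
        assert is_single_move_local_optimum(X, w, result.labels)

    @pytest.mark.parametrize("seed", range(3))
    def test_inertia_close_to_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(7, 1)) * 3
        w = rng.uniform(0.5, 2.0, size=7)
        best_inertia, _ = brute_force_best_partition(X, w, 2)
        init = weighted_kmeanspp_init(X, w, 2, rng=rng)
        result = weighted_lloyd(X, w, init)
        assert result.inertia >= best_inertia - 1e-9  # cannot beat the optimum


class TestPartialSeedKmeans:
    def test_toy_three_pairs_recovered(self):
        values = np.array([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
        X = values.reshape(-1, 1)
        w = np.ones(6)
        ids = [f"c{i}" for i in range(6)]
        best_inertia, best_labels = brute_force_best_partition(X, w, 3)
        binning = partial_seed_kmeans(
            X, w, 3, seed_contig_rows=[0, 2], rng=np.random.default_rng(0), contig_ids=ids
        )
        groups = {frozenset(v) for v in binning.bins.values()}
        assert groups == {
            frozenset({"c0", "c1"}),
            frozenset({"c2", "c3"}),
            frozenset({"c4", "c5"}),
        }
        # and that partition is the exhaustive optimum
        oracle_groups = {
            frozenset(f"c{i}" for i in np.flatnonzero(best_labels == j))
            for j in range(3)
        }
        assert groups == oracle_groups

    def test_l_equals_k_degenerate_seed_kmeans(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        binning = partial_seed_kmeans(
            X, np.ones(4), 2, [0, 2], np.random.default_rng(0), ["a", "b", "c", "d"]
        )
        groups = {frozenset(v) for v in binning.bins.values()}
        assert groups == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_l_exceeds_k_expands_k(self):
        X = np.arange(6.0).reshape(-1, 1) * 10
        binning = partial_seed_kmeans(
            X, np.ones(6), 2, [0, 1, 2, 3], np.random.default_rng(0),
            [f"c{i}" for i in range(6)],
        )
        assert binning.provenance["K"] == 4
        assert binning.n_bins == 4

    def test_l0_reduces_to_plain_kmeanspp(self):
        rng_a = np.random.default_rng(42)
        rng_b = np.random.default_rng(42)
        X = np.random.default_rng(5).normal(size=(20, 2))
        w = np.ones(20)
        ids = [f"c{i}" for i in range(20)]
        binning = partial_seed_kmeans(X, w, 3, [], rng_a, ids)
        init = weighted_kmeanspp_init(X, w, 3, [], rng_b)
        result = weighted_lloyd(X, w, init)
        expected = {ids[i]: f"k{int(l)}" for i, l in enumerate(result.labels)}
        assert binning.assignment == expected

    def test_out_of_range_seed_row_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            partial_seed_kmeans(
                np.zeros((3, 1)), np.ones(3), 2, [5], np.random.default_rng(0),
                ["a", "b", "c"],
            )


def _blob_feature_set(n_per=15, n_blobs=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blobs):
        rows.append(rng.normal(loc=b * 8.0, scale=0.3, size=(n_per, 3)))
    X = np.vstack(rows)
    n = X.shape[0]
    return FeatureSet(
        contig_ids=[f"c{i}" for i in range(n)],
        X_combo=X,
        X_cov=X[:, :1],
        X_com=X[:, 1:],
        lengths=np.full(n, 1500.0),
        T=2,
    )


class TestSelectBinNumber:
    def test_two_blobs_selects_two(self):
        fs = _blob_feature_set()
        plan = SeedPlan(
            k0=2, candidate_ks=[2, 3, 4], seed_markers=("", "", ""), seed_contigs={}
        )
        assert select_bin_number(fs, plan, np.random.default_rng(0)) == 2

    def test_single_candidate_shortcut(self):
        fs = _blob_feature_set(n_per=2, n_blobs=2)
        plan = SeedPlan(k0=2, candidate_ks=[2], seed_markers=("", "", ""), seed_contigs={})
        assert select_bin_number(fs, plan, np.random.default_rng(0)) == 2

    def test_candidates_at_or_above_n_skipped(self):
        fs = _blob_feature_set(n_per=2, n_blobs=2)  # N = 4
        plan = SeedPlan(
            k0=2, candidate_ks=[2, 3, 4, 5], seed_markers=("", "", ""), seed_contigs={}
        )
        k = select_bin_number(fs, plan, np.random.default_rng(0))
        assert k < 4

    def test_deterministic_under_seed(self):
        fs = _blob_feature_set(n_blobs=3)
        plan = SeedPlan(
            k0=2, candidate_ks=[2, 3, 4, 5], seed_markers=("", "", ""), seed_contigs={}
        )
        k1 = select_bin_number(fs, plan, np.random.default_rng(9))
        k2 = select_bin_number(fs, plan, np.random.default_rng(9))
        assert k1 == k2


@pytest.fixture(scope="module")
def features_and_plan(small_community):
    from ensemblebin.features import build_feature_set
    from ensemblebin.markers import build_seed_plan

    fs = build_feature_set(small_community.contigs, small_community.coverage)
    plan = build_seed_plan(small_community.markers, len(small_community.contigs))
    return fs, plan


class TestGenerateComponentBinnings:
    def test_exactly_twelve(self, features_and_plan):
        fs, plan = features_and_plan
        binnings = generate_component_binnings(fs, plan, plan.k0, master_seed=0)
        assert len(binnings) == 12
        by_feature = {}
        for b in binnings:
            by_feature.setdefault(b.provenance["feature"], []).append(
                b.provenance["init"]
            )
        assert set(by_feature) == {"combo", "cov", "com"}
        for inits in by_feature.values():
            assert inits == ["Q1", "Q2", "Q3", "plain"]

    def test_deterministic(self, features_and_plan):
        fs, plan = features_and_plan
        a = generate_component_binnings(fs, plan, plan.k0, master_seed=123)
        b = generate_component_binnings(fs, plan, plan.k0, master_seed=123)
        for x, y in zip(a, b):
            assert x.assignment == y.assignment

    def test_different_seeds_can_differ(self, features_and_plan):
        fs, plan = features_and_plan
        a = generate_component_binnings(fs, plan, plan.k0, master_seed=1)
        b = generate_component_binnings(fs, plan, plan.k0, master_seed=2)
        assert any(x.assignment != y.assignment for x, y in zip(a, b))

    def test_every_contig_assigned(self, features_and_plan):
        fs, plan = features_and_plan
        for binning in generate_component_binnings(fs, plan, plan.k0, master_seed=0):
            assert set(binning.assignment) == set(fs.contig_ids)


class TestSubstream:
    def test_named_streams_independent_and_reproducible(self):
        a1 = substream(7, "combo/Q1").random(4)
        a2 = substream(7, "combo/Q1").random(4)
        b = substream(7, "cov/Q1").random(4)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)


class TestBinning:
    def test_bins_derived_from_assignment(self):
        binning = Binning(assignment={"a": "x", "b": "x", "c": "y"})
        assert binning.bins == {"x": {"a", "b"}, "y": {"c"}}
        assert binning.n_bins == 2

    def test_without_contigs(self):
        binning = Binning(assignment={"a": "x", "b": "y"})
        assert binning.without_contigs({"a"}).assignment == {"b": "y"}
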