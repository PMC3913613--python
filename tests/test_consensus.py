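import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oralclust import (adjusted_rand_index, average_linkage,
                       consensus_cdf_area, consensus_cluster, item_consensus,
                       pam, robust_members, select_k)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_upgma_labels(dist, k):
    """O(n^3) agglomeration with explicit unweighted-average cluster distances."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > k:
        (a, b), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for (i, j), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new_d[(i, j)] = v
        nid = min(merged)
        for c, members in clusters.items():
            val = np.mean([dist[x, y] for x in merged for y in members])
            new_d[(min(c, nid), max(c, nid))] = val
        clusters[nid] = merged
        d = new_d
    labels = np.empty(n, dtype=int)
    for li, members in enumerate(sorted(clusters.values())):
        labels[members] = li
    return labels


def exhaustive_pam_cost(dist, k):
    n = dist.shape[0]
    return min(dist[:, list(meds)].min(axis=1).sum()
               for meds in itertools.combinations(range(n), k))


# ---------------------------------------------------------------------------
# base clusterers
# ---------------------------------------------------------------------------

class TestAverageLinkage:
    def test_two_tight_pairs(self):
        pts = np.array([[0.0], [0.1], [5.0], [5.1]])
        labels = average_linkage(squareform(pdist(pts)), 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_gives_singletons(self):
        d = squareform(pdist(np.arange(5.0)[:, None]))
        assert len(set(average_linkage(d, 5))) == 5

    def test_k_above_n_is_error(self):
        d = squareform(pdist(np.arange(3.0)[:, None]))
        with pytest.raises(ValueError):
            average_linkage(d, 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_upgma_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        for k in (2, 3, 4):
            mine = average_linkage(d, k)
            oracle = naive_upgma_labels(d, k)
            assert adjusted_rand_index(dict(enumerate(mine)),
                                       dict(enumerate(oracle))) == 1.0


class TestPam:
    def test_one_dim_pairs(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, medoids = pam(squareform(pdist(pts)), 2)
        assert labels[0] == labels[1] != labels[2]
        assert len({m < 2 for m in medoids}) == 2  # one medoid per pair

    def test_k_equals_n_costs_zero(self):
        d = squareform(pdist(np.arange(4.0)[:, None]))
        labels, medoids = pam(d, 4)
        assert sorted(medoids) == [0, 1, 2, 3]
        assert d[np.arange(4), medoids[labels]].sum() == 0

    def test_determinism(self):
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.normal(size=(9, 2))))
        l1, m1 = pam(d, 3)
        l2, m2 = pam(d, 3)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(m1, m2)

    @pytest.mark.parametrize("seed", range(20))
    def test_swap_reaches_a_single_swap_local_optimum(self, seed):
        # the SWAP contract: terminate only when no single medoid swap
        # lowers the cost; the cost can never undercut the global optimum
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        d = squareform(pdist(rng.normal(size=(n, 3))))
        labels, medoids = pam(d, k)
        mine = d[:, medoids].min(axis=1).sum()
        assert mine >= exhaustive_pam_cost(d, k) - 1e-9
        meds = list(medoids)
        for mi in range(k):
            for h in range(n):
                if h in meds:
                    continue
                trial = meds[:mi] + [h] + meds[mi + 1:]
                assert d[:, trial].min(axis=1).sum() >= mine - 1e-9


# ---------------------------------------------------------------------------
# consensus machinery
# ---------------------------------------------------------------------------

def _blob_distance(seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 0.05, size=(5, 2)),
                     rng.normal(5, 0.05, size=(5, 2))])
    names = [f"i{j}" for j in range(10)]
    return pd.DataFrame(squareform(pdist(pts)), index=names, columns=names)


class TestConsensusCluster:
    def test_two_blobs_give_binary_consensus(self):
        dist = _blob_distance()
        run = consensus_cluster(dist, "average_linkage", k_range=(2, 3),
                                h=50, p=0.8, seed=1)
        M = run.consensus[2].to_numpy()
        block = np.zeros((10, 10))
        block[:5, :5] = 1
        block[5:, 5:] = 1
        assert run.never_cosampled_pairs == 0
        np.testing.assert_array_equal(M, block)
        # the K=2 assignment recovers the blobs exactly
        lab = run.assignments[2]
        assert adjusted_rand_index(
            lab.to_dict(), {f"i{j}": j // 5 for j in range(10)}) == 1.0

    def test_full_sampling_hand_enumeration(self):
        # p=1 with a deterministic clusterer: every subsample is the full
        # item set, so M_K is exactly the 0/1 co-membership matrix
        dist = _blob_distance(3)
        run = consensus_cluster(dist, "average_linkage", k_range=(2, 3),
                                h=2, p=1.0, seed=0)
        for k in (2, 3):
            labels = average_linkage(dist.to_numpy(), k)
            expected = (labels[:, None] == labels[None, :]).astype(float)
            np.testing.assert_array_equal(run.consensus[k].to_numpy(), expected)

    def test_seeded_reproducibility(self):
        dist = _blob_distance(4)
        r1 = consensus_cluster(dist, "pam", k_range=(2, 3), h=30, p=0.7, seed=9)
        r2 = consensus_cluster(dist, "pam", k_range=(2, 3), h=30, p=0.7, seed=9)
        for k in (2, 3):
            pd.testing.assert_frame_equal(r1.consensus[k], r2.consensus[k])
        assert r1.selected_k == r2.selected_k

    def test_consensus_matrix_invariants(self):
        dist = _blob_distance(5)
        run = consensus_cluster(dist, "average_linkage", k_range=(2, 3, 4),
                                h=40, p=0.6, seed=2)
        for M in run.consensus.values():
            A = M.to_numpy()
            assert np.allclose(A, A.T)
            assert np.allclose(np.diag(A), 1.0)
            assert A.min() >= 0 and A.max() <= 1


class TestCdfAreaAndSelectK:
    def test_degenerate_matrices(self):
        ones = np.ones((4, 4))
        assert consensus_cdf_area(ones) == pytest.approx(0.0)
        zeros = np.zeros((4, 4))
        np.fill_diagonal(zeros, 1.0)
        assert consensus_cdf_area(zeros) == pytest.approx(1.0)

    def test_step_sum_equals_numeric_integration(self):
        M = np.eye(3)
        M[0, 1] = M[1, 0] = 1.0  # entries {1, 0, 0}
        # numeric integral of the ECDF over [0, 1]
        entries = np.array([1.0, 0.0, 0.0])
        xs = np.linspace(0, 1, 200_001)
        ecdf = (entries[None, :] <= xs[:, None]).mean(axis=1)
        numeric = np.trapezoid(ecdf, xs)
        assert consensus_cdf_area(M) == pytest.approx(numeric, abs=1e-4)

    def test_random_matrix_matches_integration(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(size=(6, 6))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 1.0)
        entries = M[np.triu_indices(6, 1)]
        xs = np.linspace(0, 1, 400_001)
        ecdf = (entries[None, :] <= xs[:, None]).mean(axis=1)
        numeric = np.trapezoid(ecdf, xs)
        assert consensus_cdf_area(M) == pytest.approx(numeric, abs=1e-5)

    def test_delta_area_worked_example(self):
        areas = {2: 0.5, 3: 0.9, 4: 0.92, 5: 0.93}
        k, deltas = select_k(areas)
        assert k == 3
        assert deltas[2] == pytest.approx(0.5)
        assert deltas[3] == pytest.approx(0.8)
        assert deltas[4] == pytest.approx(0.0222, abs=1e-3)
        assert deltas[5] == pytest.approx(0.0109, abs=1e-3)

    def test_flat_areas_select_two(self):
        k, _ = select_k({2: 0.6, 3: 0.6, 4: 0.6})
        assert k == 2

    def test_zero_previous_area_warns(self):
        with pytest.warns(UserWarning, match="Delta"):
            k, deltas = select_k({2: 0.0, 3: 0.4})
        assert deltas[3] == pytest.approx(0.4)
        assert k == 3


class TestItemConsensusAndRobustness:
    def test_block_diagonal_perfect(self):
        M = np.zeros((4, 4))
        M[:2, :2] = 1
        M[2:, 2:] = 1
        Mdf = pd.DataFrame(M, index=list("abcd"), columns=list("abcd"))
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        ic = item_consensus(Mdf, labels)
        assert ic.loc["a", 0] == 1.0 and ic.loc["a", 1] == 0.0
        rob = robust_members(ic, labels)
        assert rob.clusters == {0: ["a", "b"], 1: ["c", "d"]}

    def test_uninformative_item(self):
        M = np.full((5, 5), 0.5)
        np.fill_diagonal(M, 1.0)
        M[1:3, 1:3] = 1.0
        M[3:, 3:] = 1.0
        np.fill_diagonal(M, 1.0)
        names = list("abcde")
        labels = pd.Series([0, 0, 0, 1, 1], index=names)
        ic = item_consensus(pd.DataFrame(M, index=names, columns=names), labels)
        # item "a" sits at 0.5 consensus with every other item
        assert ic.loc["a", 0] == pytest.approx(0.5)
        assert ic.loc["a", 1] == pytest.approx(0.5)

    def test_hand_built_four_items(self):
        names = list("wxyz")
        M = pd.DataFrame([[1.0, 0.8, 0.3, 0.1],
                          [0.8, 1.0, 0.2, 0.4],
                          [0.3, 0.2, 1.0, 0.9],
                          [0.1, 0.4, 0.9, 1.0]], index=names, columns=names)
        labels = pd.Series([0, 0, 1, 1], index=names)
        ic = item_consensus(M, labels)
        assert ic.loc["w", 0] == pytest.approx(0.8)       # only x
        assert ic.loc["w", 1] == pytest.approx((0.3 + 0.1) / 2)
        assert ic.loc["y", 1] == pytest.approx(0.9)
        assert ic.loc["y", 0] == pytest.approx((0.3 + 0.2) / 2)

    def test_singleton_cluster_undefined(self):
        names = list("abc")
        M = pd.DataFrame(np.eye(3), index=names, columns=names)
        labels = pd.Series([0, 0, 1], index=names)
        ic = item_consensus(M, labels)
        assert np.isnan(ic.loc["c", 1])
        rob = robust_members(ic, labels)
        assert "c" in rob.excluded

    @pytest.mark.parametrize("scores, expected_robust", [
        ((0.6, 0.4), True),    # both thresholds inclusive
        ((0.59, 0.1), False),  # own-cluster too low
        ((0.9, 0.41), False),  # other cluster too high
    ])
    def test_threshold_boundaries(self, scores, expected_robust):
        ic = pd.DataFrame([list(scores), [0.1, 0.9], [0.05, 0.95]],
                          index=list("abc"), columns=[0, 1])
        labels = pd.Series([0, 1, 1], index=list("abc"))
        rob = robust_members(ic, labels)
        assert ("a" in rob.clusters.get(0, [])) is expected_robust
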