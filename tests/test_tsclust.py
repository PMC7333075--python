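"""DTW, k-medoids and membership features against independent oracles."""

import numpy as np
import pytest

from zonescreen.tsclust import (ClusterModel, DissimilarityMatrix,
                                best_clustering, dissimilarity_matrix, dtw,
                                k_medoids, membership_features,
                                standardize_subintervals, summarize_clusters)
from zonescreen.validation import dtw_brute_force, kmedoids_brute_force
from zonescreen.zone_partition import Subinterval


def random_subs(n, zone_id=1, seed=0, lmin=5, lmax=12):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(lmin, lmax + 1))
        out.append(Subinterval(zone_id, f"d{i:03d}",
                               rng.normal(size=(L, 4)), np.arange(L) * 0.1))
    return out


class TestDTW:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).normal(size=(20, 4))
        assert dtw(a, a) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(int(rng.integers(3, 15)), 4))
            b = rng.normal(size=(int(rng.integers(3, 15)), 4))
            assert dtw(a, b) == pytest.approx(dtw(b, a), abs=1e-12)

    def test_hand_computed_example(self):
        """One channel, [0,0,0] vs [1,1]: cost 3 over a 3-step path -> 1.0."""
        assert dtw(np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0])) == \
            pytest.approx(1.0)
        assert dtw(np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0]),
                   normalized=False) == pytest.approx(3.0)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            la, lb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            nch = int(rng.integers(1, 5))
            a, b = rng.normal(size=(la, nch)), rng.normal(size=(lb, nch))
            for normalized in (True, False):
                assert dtw(a, b, normalized=normalized) == pytest.approx(
                    dtw_brute_force(a, b, normalized=normalized), abs=1e-10)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            dtw(np.zeros((3, 4)), np.zeros((3, 2)))


class TestDissimilarityMatrix:
    def test_identical_subintervals_zero_matrix(self):
        ch = np.random.default_rng(3).normal(size=(6, 4))
        subs = [Subinterval(1, "a", ch, np.arange(6) * 0.1),
                Subinterval(1, "b", ch.copy(), np.arange(6) * 0.1)]
        D = dissimilarity_matrix(subs)
        np.testing.assert_array_equal(D.values, np.zeros((2, 2)))

    def test_matches_direct_pairwise_calls(self):
        subs = random_subs(4, seed=4)
        D = dissimilarity_matrix(subs)
        for i in range(4):
            for j in range(4):
                assert D.values[i, j] == pytest.approx(
                    dtw(subs[i], subs[j]), abs=1e-12)

    def test_mixed_zones_rejected(self):
        subs = random_subs(2, zone_id=1) + random_subs(2, zone_id=2, seed=9)
        with pytest.raises(ValueError, match="zones"):
            dissimilarity_matrix(subs)

    def test_standardization_pools_channels(self):
        subs = random_subs(5, seed=6)
        std, (mean, sd) = standardize_subintervals(subs)
        pooled = np.vstack([s.channels for s in std])
        np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(pooled.std(axis=0), 1.0, atol=1e-12)


class TestKMedoids:
    def euclidean_D(self, n, seed):
        pts = np.random.default_rng(seed).normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return DissimilarityMatrix(values=d, ids=[f"p{i}" for i in range(n)])

    def test_k_equals_n_zero_inertia(self):
        D = self.euclidean_D(6, seed=0)
        model = k_medoids(D, k=6, seed=1)
        assert model.inertia == 0.0
        assert sorted(model.medoid_ids.tolist()) == list(range(6))

    def test_bracketing_against_subset_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, 4))
            D = self.euclidean_D(n, seed=int(rng.integers(1000)))
            model = best_clustering(D, k=k, restarts=5,
                                    seed=int(rng.integers(1000)))
            _, opt = kmedoids_brute_force(D.values, k)
            # converged local optimum can never beat the enumerated optimum,
            # and its inertia is exactly the best-assignment inertia for its
            # own medoid set
            assert model.inertia >= opt - 1e-9
            D2 = D.values ** 2
            assert model.inertia == pytest.approx(
                float(D2[:, model.medoid_ids].min(axis=1).sum()), abs=1e-9)

    def test_inertia_history_strictly_decreasing(self):
        D = self.euclidean_D(40, seed=8)
        model = k_medoids(D, k=3, seed=2)
        hist = model.inertia_history
        assert all(b < a for a, b in zip(hist, hist[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            k_medoids(self.euclidean_D(3, seed=0), k=5)

    def test_medoids_assigned_to_own_cluster(self):
        D = self.euclidean_D(25, seed=9)
        model = k_medoids(D, k=4, seed=3)
        for c, m in enumerate(model.medoid_ids):
            assert model.assignment[m] == c


class TestBestClustering:
    def test_equals_minimum_over_manual_restarts(self):
        pts = np.random.default_rng(11).normal(size=(30, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        D = DissimilarityMatrix(values=d, ids=[f"p{i}" for i in range(30)])
        best = best_clustering(D, k=3, restarts=6, seed=5)
        manual = [k_medoids(D, k=3, seed=np.random.default_rng(c)).inertia
                  for c in np.random.SeedSequence(5).spawn(6)]
        assert best.inertia == pytest.approx(min(manual), abs=1e-12)

    def test_inertia_non_increasing_in_restarts(self):
        D_subs = random_subs(25, seed=12)
        D = dissimilarity_matrix(D_subs)
        inertias = [best_clustering(D, k=4, restarts=r, seed=6).inertia
                    for r in (1, 3, 6, 10)]
        assert all(b <= a + 1e-12 for a, b in zip(inertias, inertias[1:]))


class TestMembershipFeatures:
    def make_zone(self, zone_id, drive_ids, seed):
        rng = np.random.default_rng(seed)
        subs = []
        for d in drive_ids:
            L = int(rng.integers(5, 9))
            subs.append(Subinterval(zone_id, d, rng.normal(size=(L, 4)),
                                    np.arange(L) * 0.1))
        return dissimilarity_matrix(subs)

    def test_width_missing_and_medoid_zero(self):
        D1 = self.make_zone(1, ["a", "b", "c", "d"], seed=13)
        D2 = self.make_zone(2, ["a", "b", "e", "f"], seed=14)
        models = {1: best_clustering(D1, k=2, restarts=3, seed=1),
                  2: best_clustering(D2, k=2, restarts=3, seed=2)}
        feats = membership_features({1: D1, 2: D2}, models)
        assert feats.shape[1] == 4  # k x n_zones
        assert list(feats.columns) == ["zone1_m0", "zone1_m1",
                                       "zone2_m0", "zone2_m1"]
        # drive c never visits zone 2 -> NaN block
        assert feats.loc["c", ["zone2_m0", "zone2_m1"]].isna().all()
        # each medoid's own entry is exactly zero
        for zid, model in models.items():
            for j, m in enumerate(model.medoid_ids):
                drive = model.ids[m]
                assert feats.loc[drive, f"zone{zid}_m{j}"] == 0.0

    def test_summaries_count_all_members(self):
        D = self.make_zone(1, [f"d{i}" for i in range(10)], seed=15)
        model = best_clustering(D, k=3, restarts=3, seed=3)
        scores = {f"d{i}": i * 4 for i in range(10)}
        flags = {f"d{i}": i % 2 == 0 for i in range(10)}
        model = summarize_clusters(model, ore_scores=scores,
                                   collision_flags=flags)
        assert model.n_members.sum() == 10
        assert np.all(model.collision_rate >= 0)
        assert np.all(model.collision_rate <= 100)
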