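import itertools

import numpy as np
import pytest

from prc2net.signal_matrix import SignalMatrix
from prc2net.occupancy_clustering import (call_loss_genes,
                                          characterize_clusters,
                                          compute_wcss, default_tau_wt,
                                          kmeans_profiles)


def brute_force_min_wcss(x, k):
    """Exhaustive minimum of the k-means objective over all labelings."""
    n = len(x)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        wcss = 0.0
        for j in range(k):
            pts = x[labels == j]
            if len(pts):
                wcss += ((pts - pts.mean(0)) ** 2).sum()
        best = min(best, wcss)
    return best


class TestKmeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 6))
        a = kmeans_profiles(x, k=1, seed=0)
        np.testing.assert_allclose(a.centroids[0], x.mean(0))
        np.testing.assert_allclose(a.wcss, ((x - x.mean(0)) ** 2).sum())

    def test_two_separated_pairs_match_exhaustive_optimum(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        a = kmeans_profiles(x, k=2, seed=1, n_restarts=5)
        assert a.labels[0] == a.labels[1] and a.labels[2] == a.labels[3]
        assert a.labels[0] != a.labels[2]
        assert a.wcss == pytest.approx(brute_force_min_wcss(x, 2), abs=1e-9)

    def test_duplicate_rows_share_labels(self):
        rng = np.random.default_rng(3)
        x = np.repeat(rng.normal(size=(4, 5)), 3, axis=0)
        a = kmeans_profiles(x, k=3, seed=0, n_restarts=5)
        for i in range(0, 12, 3):
            assert len(set(a.labels[i:i + 3])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 8))
        a1 = kmeans_profiles(x, k=4, seed=9)
        a2 = kmeans_profiles(x, k=4, seed=9)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert a1.wcss == a2.wcss

    def test_wcss_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 6))
        a = kmeans_profiles(x, k=3, seed=2)
        recomputed = 0.0
        for i, lab in enumerate(a.labels):
            recomputed += ((x[i] - a.centroids[lab]) ** 2).sum()
        assert a.wcss == pytest.approx(recomputed, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_global_optimum_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 3))
        a = kmeans_profiles(x, k=2, seed=seed, n_restarts=20)
        assert a.wcss == pytest.approx(brute_force_min_wcss(x, 2), abs=1e-9)

    def test_agrees_with_sklearn_on_well_separated_data(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0]], dtype=float)
        x = np.vstack([rng.normal(c, 1.0, size=(30, 3)) for c in centers])
        ours = kmeans_profiles(x, k=3, seed=0, n_restarts=10)
        ref = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(x)
        assert ours.wcss == pytest.approx(ref.inertia_, rel=1e-9)

    def test_k_larger_than_genes_errors(self):
        with pytest.raises(ValueError):
            kmeans_profiles(np.zeros((3, 2)), k=4)


class TestCharacterize:
    def _assignment(self, centroid):
        from prc2net.occupancy_clustering import ClusterAssignment
        return ClusterAssignment(("g",), np.array([0]),
                                 np.array([centroid], dtype=float), 0.0, 0)

    def test_ratio_uses_epsilon(self):
        # WT core mean 8, KO core mean 1 -> (1+0.1)/(8+0.1)
        a = self._assignment([8.0, 8.0, 1.0, 1.0])
        (s,) = characterize_clusters(a, bins=2, core_bins=(0, 2), eps=0.1)
        assert s.ratio == pytest.approx(1.1 / 8.1)

    def test_flat_zero_centroid_has_ratio_one(self):
        a = self._assignment([0.0, 0.0, 0.0, 0.0])
        (s,) = characterize_clusters(a, bins=2, core_bins=(0, 2), eps=0.1)
        assert s.ratio == 1.0

    def test_equal_halves_have_ratio_one(self):
        a = self._assignment([3.0, 5.0, 3.0, 5.0])
        (s,) = characterize_clusters(a, bins=2, core_bins=(0, 2), eps=0.1)
        assert s.ratio == pytest.approx(1.0)


def _matrix(values, library=1_000_000):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"g{i}" for i in range(values.shape[0]))
    return SignalMatrix(ids, values, 100, values.shape[1] * 50, "rpm", library)


class TestCallLossGenes:
    def test_identical_conditions_yield_no_loss(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, size=(30, 4))
        wt = _matrix(vals)
        calls = call_loss_genes(wt, wt, k=3, core_halfwidth=100, n_consensus=3)
        assert not any(c.is_loss for c in calls)

    def test_zero_wt_yields_no_loss(self):
        rng = np.random.default_rng(1)
        wt = _matrix(np.zeros((20, 4)))
        ko = _matrix(rng.uniform(0, 50, size=(20, 4)))
        calls = call_loss_genes(wt, ko, k=2, core_halfwidth=100, n_consensus=3)
        assert not any(c.is_loss for c in calls)

    def _planted(self, seed=0, n=60):
        # 40% loss genes: the default tau (60th percentile of WT scores)
        # then falls in the gap between background and marked genes
        rng = np.random.default_rng(seed)
        n_loss = int(n * 0.4)
        wt = np.full((n, 4), 2.0) + rng.uniform(0, 0.5, (n, 4))
        ko = wt.copy()
        wt[:n_loss] += 40.0  # strong promoter signal
        ko[:n_loss] += 2.0   # nearly eliminated in KO
        ko[n_loss:] = wt[n_loss:]
        return _matrix(wt), _matrix(ko)

    def test_recovers_planted_split(self):
        wt, ko = self._planted()
        calls = call_loss_genes(wt, ko, k=3, core_halfwidth=200, n_consensus=5)
        loss = {c.gene_id for c in calls if c.is_loss}
        assert loss == {f"g{i}" for i in range(24)}

    def test_loss_set_monotone_in_rho_and_tau(self):
        wt, ko = self._planted(seed=2)
        def loss_set(rho, tau):
            calls = call_loss_genes(wt, ko, k=3, core_halfwidth=200,
                                    n_consensus=3, rho=rho, tau_wt=tau)
            return {c.gene_id for c in calls if c.is_loss}
        assert loss_set(0.1, 5.0) <= loss_set(0.3, 5.0) <= loss_set(0.9, 5.0)
        assert loss_set(0.3, 50.0) <= loss_set(0.3, 20.0) <= loss_set(0.3, 1.0)

    def test_relabeling_invariance_across_seeds(self):
        # different consensus base seeds permute cluster labels arbitrarily,
        # but the called loss set is stable on well-separated data
        wt, ko = self._planted(seed=3)
        sets = []
        for base in (0, 17, 91):
            calls = call_loss_genes(wt, ko, k=3, core_halfwidth=200,
                                    n_consensus=4, base_seed=base)
            sets.append(frozenset(c.gene_id for c in calls if c.is_loss))
        assert len(set(sets)) == 1

    def test_geometry_mismatch_errors(self):
        wt, _ = self._planted()
        bad = _matrix(np.zeros((60, 8)))
        with pytest.raises(ValueError):
            call_loss_genes(wt, bad)


def test_default_tau_ignores_zero_scores():
    scores = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    # 60th percentile of the five nonzero scores
    assert default_tau_wt(scores) == pytest.approx(np.percentile([1, 2, 3, 4, 5], 60))
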