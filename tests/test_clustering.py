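"""Graph construction, spectral clustering, agreement metrics, stability."""

import numpy as np
import pytest
from scipy.special import gammaln

import ensemble_dynamics as ed
from ensemble_dynamics.clustering import (
    StabilityReport,
    cluster_quality,
    knn_cosine_graph,
    select_parameters,
    silhouette_filter,
    spectral_cluster,
    stability_scan,
)
from ensemble_dynamics.datatypes import ValidationError


# ---------------------------------------------------------------------------
# independent brute-force oracles

def ari_pair_counting(a, b):
    """ARI via explicit pair counting (independent of contingency sums)."""
    a, b = np.asarray(a), np.asarray(b)
    iu, ju = np.triu_indices(a.size, k=1)
    sa = a[iu] == a[ju]
    sb = b[iu] == b[ju]
    n11 = np.sum(sa & sb)
    n10 = np.sum(sa & ~sb)
    n01 = np.sum(~sa & sb)
    n00 = np.sum(~sa & ~sb)
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def ami_contingency(a, b):
    """AMI via the expected-MI hypergeometric formula, computed from scratch."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    ua, ub = np.unique(a), np.unique(b)
    if ua.size == 1 and ub.size == 1:
        return 1.0
    ai = np.array([np.sum(a == u) for u in ua], dtype=float)
    bj = np.array([np.sum(b == u) for u in ub], dtype=float)
    mi = 0.0
    for i, u in enumerate(ua):
        for j, v in enumerate(ub):
            nij = np.sum((a == u) & (b == v))
            if nij:
                mi += nij / n * np.log(n * nij / (ai[i] * bj[j]))
    h_a = -np.sum(ai / n * np.log(ai / n))
    h_b = -np.sum(bj / n * np.log(bj / n))
    emi = 0.0
    for i in range(ua.size):
        for j in range(ub.size):
            lo = int(max(1, ai[i] + bj[j] - n))
            hi = int(min(ai[i], bj[j]))
            for nij in range(lo, hi + 1):
                term = np.exp(
                    gammaln(ai[i] + 1) + gammaln(bj[j] + 1)
                    + gammaln(n - ai[i] + 1) + gammaln(n - bj[j] + 1)
                    - gammaln(n + 1) - gammaln(nij + 1)
                    - gammaln(ai[i] - nij + 1) - gammaln(bj[j] - nij + 1)
                    - gammaln(n - ai[i] - bj[j] + nij + 1)
                )
                emi += term * (nij / n) * np.log(n * nij / (ai[i] * bj[j]))
    denom = 0.5 * (h_a + h_b) - emi
    if denom == 0:
        return 0.0
    return (mi - emi) / denom


def random_label_pair(rng, n_max=30):
    n = int(rng.integers(5, n_max + 1))
    while True:
        a = rng.integers(0, int(rng.integers(2, 6)), size=n)
        b = rng.integers(0, int(rng.integers(2, 6)), size=n)
        if np.unique(a).size > 1 and np.unique(b).size > 1:
            return a, b


# ---------------------------------------------------------------------------

class TestKnnCosineGraph:
    def test_antipodal_groups_disconnect(self):
        rng = np.random.default_rng(0)
        g1 = np.array([1.0, 0.0]) + 0.01 * rng.standard_normal((10, 2))
        g2 = np.array([-1.0, 0.0]) + 0.01 * rng.standard_normal((10, 2))
        A = knn_cosine_graph(np.vstack([g1, g2]), knn=3)
        from scipy.sparse.csgraph import connected_components
        n_comp, labels = connected_components(A > 0, directed=False)
        assert n_comp == 2
        assert len(set(labels[:10])) == 1 and labels[0] != labels[10]

    def test_symmetric_zero_diagonal(self):
        X = np.random.default_rng(1).standard_normal((20, 4))
        A = knn_cosine_graph(X, knn=4)
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_full_knn_gives_complete_graph(self):
        X = np.random.default_rng(2).standard_normal((12, 3))
        A = knn_cosine_graph(X, knn=11)
        assert np.all(A[~np.eye(12, dtype=bool)] == 1)

    def test_zero_vector_rejected(self):
        X = np.vstack([np.zeros(3), np.ones((5, 3))])
        with pytest.raises(ValidationError):
            knn_cosine_graph(X, knn=2)


class TestSpectralCluster:
    def test_two_disconnected_cliques_recovered(self):
        A = np.zeros((20, 20))
        A[:10, :10] = 1
        A[10:, 10:] = 1
        np.fill_diagonal(A, 0)
        sol = spectral_cluster(A, k=2, seed=0)
        truth = np.array([0] * 10 + [1] * 10)
        assert ed.partition_agreement(sol.labels, truth)["ari"] == 1.0

    def test_k_blocks_exact_recovery(self):
        """Block-diagonal affinity with k blocks is recovered exactly."""
        rng = np.random.default_rng(4)
        sizes = [8, 12, 6, 9]
        n = sum(sizes)
        A = np.zeros((n, n))
        truth = np.zeros(n, dtype=int)
        o = 0
        for b, s in enumerate(sizes):
            A[o:o + s, o:o + s] = 1
            truth[o:o + s] = b
            o += s
        np.fill_diagonal(A, 0)
        sol = spectral_cluster(A, k=4, seed=1)
        assert ed.partition_agreement(sol.labels, truth)["ari"] == 1.0

    def test_k1_single_label(self):
        A = np.ones((5, 5)) - np.eye(5)
        sol = spectral_cluster(A, k=1, seed=0)
        assert np.all(sol.labels == 0)

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValidationError):
            spectral_cluster(np.ones((3, 3)) - np.eye(3), k=5, seed=0)


class TestPartitionAgreement:
    def test_identical_labelings(self):
        lab = np.array([0, 0, 1, 1, 2, 2])
        res = ed.partition_agreement(lab, lab)
        assert res["ari"] == 1.0 and res["ami"] == pytest.approx(1.0)

    def test_single_cluster_vs_structure_is_chance(self):
        res = ed.partition_agreement(np.array([0, 0, 1, 1, 2, 2]), np.zeros(6, int))
        assert res["ari"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValidationError):
            ed.partition_agreement(np.zeros(3), np.zeros(4))

    def test_six_item_case_matches_oracle(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 0, 0, 1, 1, 1])
        res = ed.partition_agreement(a, b)
        assert res["ari"] == pytest.approx(ari_pair_counting(a, b), abs=1e-12)
        assert res["ami"] == pytest.approx(ami_contingency(a, b), abs=1e-12)

    def test_fuzz_against_brute_force(self):
        """200 random label pairs agree with the pair-counting/EMI oracles."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b = random_label_pair(rng)
            res = ed.partition_agreement(a, b)
            assert res["ari"] == pytest.approx(ari_pair_counting(a, b), abs=1e-12)
            assert res["ami"] == pytest.approx(ami_contingency(a, b), abs=1e-12)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b = random_label_pair(rng)
            r1 = ed.partition_agreement(a, b)
            r2 = ed.partition_agreement(b, a)
            assert r1["ari"] == pytest.approx(r2["ari"], abs=1e-12)
            assert r1["ami"] == pytest.approx(r2["ami"], abs=1e-12)
            # relabeling clusters must not matter
            perm = rng.permutation(6)
            r3 = ed.partition_agreement(perm[a], b)
            assert r1["ari"] == pytest.approx(r3["ari"], abs=1e-12)
            assert r1["ami"] == pytest.approx(r3["ami"], abs=1e-10)


def _blob_features(rng, n_per=20, k=3, dim=6, noise=0.05):
    centers = rng.standard_normal((k, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    X = np.vstack([c + noise * rng.standard_normal((n_per, dim)) for c in centers])
    truth = np.repeat(np.arange(k), n_per)
    return X, truth


class TestStabilityScan:
    def test_planted_k_maximizes_mean_ari(self):
        rng = np.random.default_rng(0)
        X, _ = _blob_features(rng, n_per=20, k=3)
        rep = stability_scan(X, k_range=(2, 3, 4, 5), knn_range=(8,),
                             n_boot=20, seed=1)
        means = {k: rep.grid[(k, 8)]["ari_mean"] for k in (2, 3, 4, 5)}
        assert max(means, key=means.get) == 3

    def test_noise_features_markedly_less_stable_than_planted(self):
        """Isotropic noise never reaches the near-perfect stability of
        well-separated planted structure at the same (k, knn)."""
        rng = np.random.default_rng(1)
        Xp, _ = _blob_features(rng, n_per=20, k=3)
        Xn = rng.standard_normal(Xp.shape)
        rp = stability_scan(Xp, (3,), (8,), n_boot=20, seed=2)
        rn = stability_scan(Xn, (3,), (8,), n_boot=20, seed=2)
        assert rp.grid[(3, 8)]["ari_mean"] > 0.9
        assert rn.grid[(3, 8)]["ari_mean"] < rp.grid[(3, 8)]["ari_mean"] - 0.2

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X, _ = _blob_features(rng, n_per=10, k=2)
        r1 = stability_scan(X, (2, 3), (5,), n_boot=5, seed=3)
        r2 = stability_scan(X, (2, 3), (5,), n_boot=5, seed=3)
        assert r1.grid == r2.grid

    def test_planted_exceeds_noise_at_planted_k(self):
        """Paired over seeds: planted-structure stability beats matched noise."""
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            Xp, _ = _blob_features(rng, n_per=15, k=3)
            Xn = rng.standard_normal(Xp.shape)
            rp = stability_scan(Xp, (3,), (8,), n_boot=10, seed=seed)
            rn = stability_scan(Xn, (3,), (8,), n_boot=10, seed=seed)
            wins += rp.grid[(3, 8)]["ari_mean"] > rn.grid[(3, 8)]["ari_mean"]
        assert wins == 8

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValidationError):
            stability_scan(np.random.default_rng(0).standard_normal((20, 3)),
                           (2,), (4,), n_boot=1, seed=0)


class TestSelectParameters:
    def _report(self, grid):
        return StabilityReport(grid=grid)

    def test_dominant_cell_wins_both(self):
        grid = {
            (2, 5): dict(ari_mean=0.5, ari_sd=0.2, ami_mean=0.5, ami_sd=0.2, n_boot=10),
            (3, 5): dict(ari_mean=0.9, ari_sd=0.05, ami_mean=0.9, ami_sd=0.05, n_boot=10),
        }
        sel = select_parameters(self._report(grid))
        assert sel["by_mean"] == (3, 5) and sel["by_mean_over_sd"] == (3, 5)

    def test_tie_breaks_to_smallest_k_then_knn(self):
        cell = dict(ari_mean=0.8, ari_sd=0.1, ami_mean=0.8, ami_sd=0.1, n_boot=10)
        grid = {(3, 10): dict(cell), (2, 20): dict(cell), (2, 10): dict(cell)}
        sel = select_parameters(self._report(grid))
        assert sel["by_mean"] == (2, 10) and sel["by_mean_over_sd"] == (2, 10)

    def test_perfectly_stable_cell_dominates_ratio(self):
        grid = {
            (2, 5): dict(ari_mean=0.9, ari_sd=0.01, ami_mean=0.9, ami_sd=0.01, n_boot=10),
            (7, 5): dict(ari_mean=1.0, ari_sd=0.0, ami_mean=1.0, ami_sd=0.0, n_boot=10),
        }
        sel = select_parameters(self._report(grid))
        assert sel["by_mean_over_sd"] == (7, 5)


class TestClusterQuality:
    def test_identical_vectors_give_intra_one(self):
        rng = np.random.default_rng(0)
        v1, v2 = rng.standard_normal(5), rng.standard_normal(5)
        X = np.vstack([v1, v1, v1, v2, v2, v2])
        res = cluster_quality(X, np.array([0, 0, 0, 1, 1, 1]))
        assert res["intra"] == pytest.approx(1.0)

    def test_random_labels_intra_matches_inter(self):
        """On exchangeable data, random labels give intra ~ inter (the ratio
        itself is ill-conditioned when both approach zero)."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        res = cluster_quality(X, rng.integers(0, 3, 200))
        assert res["intra"] == pytest.approx(res["inter"], abs=0.05)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        labels = rng.integers(0, 3, 20)
        res = cluster_quality(X, labels)
        intra, inter = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                r = np.corrcoef(X[i], X[j])[0, 1]
                (intra if labels[i] == labels[j] else inter).append(r)
        assert res["intra"] == pytest.approx(np.mean(intra), abs=1e-12)
        assert res["inter"] == pytest.approx(np.mean(inter), abs=1e-12)


class TestSilhouetteFilter:
    def test_separated_blobs_all_retained(self):
        rng = np.random.default_rng(0)
        X, _ = _blob_features(rng, n_per=15, k=3, noise=0.03)
        res = silhouette_filter(X, k=3, knn=8, n_iter=20, min_pass=19, seed=0)
        assert res["retained"].all()

    def test_midpoint_cell_dropped(self):
        # exact symmetry: a probe equidistant (cosine) from both clusters has
        # silhouette exactly 0 and can never pass the s > 0 rule
        c1 = np.array([1.0, 0.0, 0.0])
        c2 = np.array([0.0, 1.0, 0.0])
        X = np.vstack([np.tile(c1, (15, 1)), np.tile(c2, (15, 1)), (c1 + c2) / 2])
        res = silhouette_filter(X, k=2, knn=5, n_iter=20, min_pass=19, seed=0)
        assert res["retained"][:30].all()
        assert not res["retained"][30]
        assert res["pass_counts"][30] == 0

    def test_four_point_silhouette_matches_hand_computation(self):
        # two tight pairs along different directions, cosine distance
        X = np.array([[1.0, 0.0], [0.98, 0.05], [0.0, 1.0], [0.05, 0.97]])
        labels = np.array([0, 0, 1, 1])
        from sklearn.metrics import silhouette_samples
        s = silhouette_samples(X, labels, metric="cosine")

        def cosd(u, v):
            return 1 - np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))

        for i in range(4):
            mate = [j for j in range(4) if labels[j] == labels[i] and j != i][0]
            others = [j for j in range(4) if labels[j] != labels[i]]
            a = cosd(X[i], X[mate])
            b = np.mean([cosd(X[i], X[j]) for j in others])
            assert s[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)

    def test_min_pass_exceeding_iters_rejected(self):
        with pytest.raises(ValidationError):
            silhouette_filter(np.random.default_rng(0).standard_normal((20, 3)),
                              k=2, knn=4, n_iter=5, min_pass=6, seed=0)
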