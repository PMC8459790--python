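"""Supervised attribute clustering: refinement, sign-flipping, oracle
agreement, partition and projection properties."""

import numpy as np
import pytest

from mfsacec.filters import FILTER_IDS, FilterSpec, GeneSubset, score_matrix, select_top_p
from mfsacec.sac import (
    ReducedSubDataset,
    cluster_subset,
    project,
    refine_cluster,
    select_top_q,
)

from _sac_oracle import sac_oracle

SCALE_INVARIANT = ("pearson", "snr", "ttest", "fisher", "chi2", "mi")


def _pool(X, classes, fid="pearson", P=None):
    spec = FilterSpec(fid)
    scores = score_matrix(X, classes, spec)
    return select_top_p(scores, P or X.shape[1]), spec


class TestRefineCluster:
    def test_exact_copy_is_not_absorbed(self):
        # TR+ = 2g has the same Pearson as g (scale invariance): no strict
        # improvement, so the duplicate stays in the pool
        rng = np.random.default_rng(0)
        classes = np.array(["a"] * 20 + ["b"] * 20)
        g = (classes == "b") + rng.normal(scale=0.3, size=40)
        X = np.column_stack([g, g])
        pool, spec = _pool(X, classes)
        cluster, rep, remaining = refine_cluster(pool, X, classes, spec)
        assert cluster.members == [0]
        assert cluster.count == 1
        assert len(remaining) == 1

    def test_anti_correlated_gene_absorbed_with_negative_sign(self):
        # g2 = -signal + noise merges via the sign-flipped branch and the
        # averaged representative beats either member (noise averaging)
        rng = np.random.default_rng(1)
        classes = np.array(["a"] * 20 + ["b"] * 20)
        signal = (classes == "b").astype(float)
        g1 = signal + rng.normal(scale=0.5, size=40)
        g2 = -signal + rng.normal(scale=0.5, size=40)
        X = np.column_stack([g1, g2])
        pool, spec = _pool(X, classes)
        cluster, rep, _ = refine_cluster(pool, X, classes, spec)
        assert cluster.count == 2
        assert cluster.signs[0] == 1 and cluster.signs[1] == -1
        member_scores = score_matrix(X, classes, spec)
        assert rep.score > member_scores.max()

    def test_seed_has_positive_sign_and_highest_score(self):
        rng = np.random.default_rng(2)
        classes = np.array(["a"] * 10 + ["b"] * 10)
        X = rng.normal(size=(20, 6))
        pool, spec = _pool(X, classes, "fisher")
        cluster, _, _ = refine_cluster(pool, X, classes, spec)
        assert cluster.members[0] == int(pool.indices[0])
        assert cluster.signs[0] == 1

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            refine_cluster(
                GeneSubset(indices=np.array([], dtype=int), scores=np.array([])),
                np.zeros((4, 2)), np.array(["a", "a", "b", "b"]), FilterSpec("pearson"),
            )

    def test_accepted_merge_scores_strictly_increase(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            classes = np.array(["a"] * 12 + ["b"] * 12)
            X = rng.normal(size=(24, 8)) + 0.8 * (classes == "b")[:, None] * rng.normal(size=8)
            for fid in ("pearson", "fisher"):
                pool, spec = _pool(X, classes, fid)
                cluster, rep, _ = refine_cluster(pool, X, classes, spec)
                trace = cluster.score_trace
                assert all(b > a for a, b in zip(trace, trace[1:]))
                assert rep.pre_division_score >= trace[0]

    @pytest.mark.parametrize("fid", SCALE_INVARIANT)
    def test_division_preserves_score_for_scale_invariant_filters(self, fid):
        rng = np.random.default_rng(4)
        classes = np.array(["a"] * 15 + ["b"] * 15)
        X = rng.normal(size=(30, 6)) + (classes == "b")[:, None] * rng.normal(size=6)
        pool, spec = _pool(X, classes, fid)
        _, rep, _ = refine_cluster(pool, X, classes, spec)
        assert rep.score == pytest.approx(rep.pre_division_score, rel=1e-9, abs=1e-9)


class TestClusterSubset:
    def test_single_gene_pool_gives_one_singleton(self):
        classes = np.array(["a", "a", "b", "b"])
        X = np.array([[0.0], [0.1], [1.0], [1.2]])
        pool, spec = _pool(X, classes)
        clusters = cluster_subset(pool, X, classes, spec)
        assert len(clusters) == 1 and clusters[0][0].count == 1

    def test_partition_property_random_sweep(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            u = int(rng.integers(6, 14))
            v = int(rng.integers(2, 9))
            X = rng.normal(size=(u, v))
            y = np.array(["a"] * (u // 2) + ["b"] * (u - u // 2))
            pool, spec = _pool(X, y, "pearson")
            clusters = cluster_subset(pool, X, y, spec)
            members = [m for c, _ in clusters for m in c.members]
            assert sorted(members) == list(range(v))       # union = pool
            assert len(set(members)) == len(members)       # disjoint
            assert sum(c.count for c, _ in clusters) == v  # counts add up
            assert [c.order for c, _ in clusters] == list(range(1, len(clusters) + 1))

    def test_correlated_signal_clusters_larger_than_noise(self):
        # chance correlations let noise genes merge occasionally, but a
        # correlated signal block should concentrate into far larger
        # clusters than independent noise does
        y = np.array(["a"] * 20 + ["b"] * 20)
        noise_max, signal_max = [], []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            Xn = rng.normal(size=(40, 12))
            pool, spec = _pool(Xn, y, "pearson")
            noise_max.append(max(c.count for c, _ in cluster_subset(pool, Xn, y, spec)))

            Xs = 2.0 * (y == "b").astype(float)[:, None] + 0.8 * rng.normal(size=(40, 12))
            pool, spec = _pool(Xs, y, "pearson")
            signal_max.append(max(c.count for c, _ in cluster_subset(pool, Xs, y, spec)))
        assert np.mean(signal_max) > np.mean(noise_max)
        assert np.mean(signal_max) >= 8  # most of the block coalesces

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10)
        pool, spec = _pool(X, y, "mi")
        c1 = cluster_subset(pool, X, y, spec)
        c2 = cluster_subset(pool, X, y, spec)
        assert [(c.members, c.signs) for c, _ in c1] == [(c.members, c.signs) for c, _ in c2]
        for (_, r1), (_, r2) in zip(c1, c2):
            assert np.array_equal(r1.vector, r2.vector)


class TestOracleAgreement:
    @pytest.mark.parametrize("fid", FILTER_IDS)
    def test_matches_naive_transcription_small(self, fid):
        rng = np.random.default_rng(7)
        for trial in range(5):
            u = int(rng.integers(6, 13))
            v = int(rng.integers(2, 9))
            X = rng.normal(size=(u, v))
            y = np.array(["a"] * (u // 2) + ["b"] * (u - u // 2))
            spec = FilterSpec(fid)
            scores = score_matrix(X, y, spec)
            pool = select_top_p(scores, v)
            ours = cluster_subset(pool, X, y, spec)
            ref = sac_oracle(pool.indices, pool.scores, X, y, spec)
            assert len(ours) == len(ref)
            for (c, rep), (members, signs, count, vec, score) in zip(ours, ref):
                assert c.members == members
                assert c.signs == signs
                assert c.count == count
                assert np.array_equal(rep.vector, vec)
                assert rep.score == score


class TestSelectTopQ:
    def _clusters(self):
        rng = np.random.default_rng(8)
        y = np.array(["a"] * 12 + ["b"] * 12)
        X = rng.normal(size=(24, 8)) + (y == "b")[:, None] * rng.normal(size=8)
        pool, spec = _pool(X, y, "fisher")
        return cluster_subset(pool, X, y, spec)

    def test_q_one_keeps_best(self):
        clusters = self._clusters()
        rsd = select_top_q(clusters, 1)
        best = max(r.score for _, r in clusters)
        assert rsd.clusters[0][1].score == best

    def test_q_all_is_identity_up_to_order(self):
        clusters = self._clusters()
        rsd = select_top_q(clusters, len(clusters))
        assert {c.order for c, _ in rsd.clusters} == {c.order for c, _ in clusters}

    def test_score_tie_prefers_earlier_cluster(self):
        from mfsacec.sac import Cluster, Representative
        mk = lambda order, score: (
            Cluster(members=[order], signs=[1], order=order),
            Representative(vector=None, score=score, pre_division_score=score,
                           cluster=None),
        )
        rsd = select_top_q([mk(1, 0.9), mk(2, 0.9), mk(3, 0.5)], 2)
        assert [c.order for c, _ in rsd.clusters] == [1, 2]

    def test_q_exceeding_clusters_names_context(self):
        clusters = self._clusters()
        with pytest.raises(ValueError, match="replicate"):
            select_top_q(clusters, len(clusters) + 1, filter_id="fisher", replicate=3)


class TestProject:
    def test_training_sample_reproduces_representative_coordinate(self):
        rng = np.random.default_rng(9)
        y = np.array(["a"] * 12 + ["b"] * 12)
        X = rng.normal(size=(24, 8)) + (y == "b")[:, None] * rng.normal(size=8)
        pool, spec = _pool(X, y, "pearson")
        clusters = cluster_subset(pool, X, y, spec)
        rsd = select_top_q(clusters, min(3, len(clusters)), n_genes=8)
        F = project(rsd, X)
        for q, (_, rep) in enumerate(rsd.clusters):
            assert np.array_equal(F[:, q], rep.vector)

    def test_signed_mean_hand_value(self):
        from mfsacec.sac import Cluster, Representative
        cluster = Cluster(members=[0, 1], signs=[1, -1], order=1)
        rep = Representative(vector=None, score=0.0, pre_division_score=0.0, cluster=cluster)
        rsd = ReducedSubDataset(clusters=[(cluster, rep)], filter_id="pearson",
                                replicate=0, n_genes=2)
        assert project(rsd, np.array([4.0, 1.0])) == pytest.approx([1.5])

    def test_singleton_cluster_is_identity(self):
        from mfsacec.sac import Cluster, Representative
        cluster = Cluster(members=[1], signs=[1], order=1)
        rep = Representative(vector=None, score=0.0, pre_division_score=0.0, cluster=cluster)
        rsd = ReducedSubDataset(clusters=[(cluster, rep)], filter_id="pearson",
                                replicate=0, n_genes=3)
        assert project(rsd, np.array([4.0, 7.0, 2.0])) == pytest.approx([7.0])

    def test_misaligned_vector_rejected(self):
        from mfsacec.sac import Cluster, Representative
        cluster = Cluster(members=[0], signs=[1], order=1)
        rep = Representative(vector=None, score=0.0, pre_division_score=0.0, cluster=cluster)
        rsd = ReducedSubDataset(clusters=[(cluster, rep)], filter_id="pearson",
                                replicate=0, n_genes=5)
        with pytest.raises(ValueError):
            project(rsd, np.zeros(4))


class TestSerialization:
    def test_rsd_round_trips_through_dict(self):
        rng = np.random.default_rng(10)
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = rng.normal(size=(20, 6)) + (y == "b")[:, None] * rng.normal(size=6)
        pool, spec = _pool(X, y, "snr")
        clusters = cluster_subset(pool, X, y, spec)
        rsd = select_top_q(clusters, 2, filter_id="snr", replicate=4, n_genes=6)
        back = ReducedSubDataset.from_dict(rsd.to_dict())
        assert back.filter_id == "snr" and back.replicate == 4
        assert [(c.members, c.signs) for c, _ in back.clusters] == [
            (c.members, c.signs) for c, _ in rsd.clusters
        ]
        S = rng.normal(size=(3, 6))
        assert np.array_equal(project(back, S), project(rsd, S))
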