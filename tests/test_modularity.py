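"""Modularity, community detection, and consensus-rank tests."""

import numpy as np
import pytest

from myotask._exceptions import MyotaskError, ValidationError
from myotask.modularity import (
    ModularityParams,
    Partition,
    consensus_model_rank,
    detect_communities,
    modularity_mono,
    modularity_multi,
)


def two_triangles():
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return a


def sbm(rng, n_per_block=10, p_in=0.9, p_out=0.05):
    n = 2 * n_per_block
    g = np.repeat([0, 1], n_per_block)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < (p_in if g[i] == g[j] else p_out):
                a[i, j] = a[j, i] = 1.0
    return a, g


class TestModularityMono:
    def test_all_in_one_is_zero(self, rng):
        a = rng.uniform(0, 1, (7, 7))
        a = np.triu(a, 1)
        a = a + a.T
        assert modularity_mono(a, Partition((1,) * 7)) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_half(self):
        assert modularity_mono(two_triangles(), Partition((1, 1, 1, 2, 2, 2))) == \
            pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_brute_force_summation(self, n, rng):
        a = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.6)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            a[0, 1] = a[1, 0] = 1.0
        g = rng.integers(1, 4, n)
        two_m = a.sum()
        k = a.sum(axis=1)
        brute = sum((a[i, j] - k[i] * k[j] / two_m) * (g[i] == g[j])
                    for i in range(n) for j in range(n)) / two_m
        assert modularity_mono(a, Partition(tuple(g))) == pytest.approx(brute, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(MyotaskError):
            modularity_mono(np.zeros((3, 3)), Partition((1, 1, 1)))


class TestModularityMulti:
    def test_single_layer_reduces_to_mono(self):
        a = two_triangles()
        p = Partition((1, 1, 1, 2, 2, 2))
        assert modularity_multi([a], [p]) == pytest.approx(
            modularity_mono(a, p), abs=1e-12)

    def test_identical_layers_omega_zero_is_mean_mono(self):
        a = two_triangles()
        p = Partition((1, 1, 1, 2, 2, 2))
        q = modularity_multi([a, a, a], [p, p, p], ModularityParams(1.0, 0.0))
        assert q == pytest.approx(modularity_mono(a, p), abs=1e-12)

    def test_q_monotone_in_omega_for_consistent_partitions(self):
        a = two_triangles()
        p = Partition((1, 1, 1, 2, 2, 2))
        qs = [modularity_multi([a, a], [p, p], ModularityParams(1.0, om))
              for om in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(q2 > q1 for q1, q2 in zip(qs, qs[1:]))

    def test_hand_expansion_on_four_nodes(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        p = Partition((1, 1, 2, 2))
        # within a block {i,j}: A contributes 2, the null kk'/2m terms
        # contribute 4 * (1*1/4) = 1 (diagonal included), so A - P = 1
        expected = ((2 - 1) + (2 - 1)) / 4
        assert modularity_mono(a, p) == pytest.approx(expected, abs=1e-12)
        assert modularity_multi([a, a], [p, p], ModularityParams(1.0, 0.0)) == \
            pytest.approx(expected, abs=1e-12)


class TestDetectCommunities:
    def test_two_triangles(self):
        p = detect_communities(two_triangles(), seed=0, n_repeats=10)
        assert p.n_communities == 2
        assert p.assignment[0] == p.assignment[1] == p.assignment[2]
        assert p.assignment[3] == p.assignment[4] == p.assignment[5]

    def test_complete_graph_single_community(self):
        p = detect_communities(np.ones((6, 6)) - np.eye(6), seed=0, n_repeats=5)
        assert p.n_communities == 1

    def test_planted_two_block_recovery_rate(self):
        hits = 0
        for s in range(20):
            a, g = sbm(np.random.default_rng(s))
            p = detect_communities(a, seed=s, n_repeats=20)
            lab = np.asarray(p.assignment)
            ok = (p.n_communities == 2 and len(set(lab[:10])) == 1
                  and len(set(lab[10:])) == 1 and lab[0] != lab[10])
            hits += ok
        assert hits >= 19  # >= 95% of seeds

    def test_never_below_all_in_one(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        a = np.triu(a, 1)
        a = a + a.T
        p = detect_communities(a, seed=0, n_repeats=5)
        assert modularity_mono(a, p) >= -1e-12

    def test_edgeless_rejected(self):
        with pytest.raises(ValidationError):
            detect_communities(np.zeros((4, 4)))


class TestConsensus:
    def test_identical_partitions_fixed_point(self):
        parts = [Partition((1, 1, 1, 2, 2, 2, 3, 3, 3))] * 4
        rank, trace = consensus_model_rank(parts, seed=0)
        assert rank == 3
        assert trace["agreement"] == 1.0

    def test_noisy_partitions_recover_three_blocks(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            parts = []
            for _ in range(6):
                lab = np.repeat([1, 2, 3], 3)
                flip = rng.random(9) < 0.1
                lab[flip] = rng.integers(1, 4, flip.sum())
                parts.append(Partition(tuple(lab)))
            rank, _ = consensus_model_rank(parts, seed=s)
            hits += rank == 3
        assert hits >= 9  # >= 90% of seeds

    def test_idempotence(self):
        parts = [Partition((1, 1, 2, 2, 3, 3)), Partition((1, 1, 2, 2, 3, 3))]
        rank1, trace = consensus_model_rank(parts, seed=0)
        consensus = Partition(tuple(trace["consensus_assignment"]))
        rank2, _ = consensus_model_rank([consensus, consensus], seed=1)
        assert rank1 == rank2

    def test_inconsistent_node_sets_rejected(self):
        with pytest.raises(ValidationError):
            consensus_model_rank([Partition((1, 2)), Partition((1, 2, 3))])


class TestRankSelection:
    def test_planted_rank_three_two(self, rank32_sparse_tensor):
        from myotask.modularity import select_model_rank

        _, sp, _ = rank32_sparse_tensor
        rank = select_model_rank(sp, n_repeats=20, seed=0)
        assert rank.spatial == 3
        assert rank.temporal == 2
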