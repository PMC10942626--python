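"""Similarity-analysis (generalisability) tests."""

import numpy as np
import pytest

from myotask._exceptions import ValidationError
from myotask.coupling import CouplingTensor
from myotask.robustness import (
    fisher_summary,
    leave_n_out,
    match_and_correlate,
    random_ablation,
)
from myotask.trifactor import FitOptions, snm3f_fit


class _Dec:
    def __init__(self, spatial, temporal):
        self.spatial_factors = spatial
        self.temporal_factors = temporal


def planted_tensor_with_labels(rng, k=12, t=8, participants=3):
    w = rng.uniform(0, 1, (2, t)) * (rng.random((2, t)) < 0.6)
    v = rng.uniform(0, 1, (3, k)) * (rng.random((3, k)) < 0.6)
    s = rng.uniform(0, 1, (participants, 2, 3))
    values = np.einsum("lij,it,jk->ktl", s, w, v)
    from itertools import combinations
    mpairs = list(combinations(range(5), 2))[:k]
    tpairs = [(a, b) for a in range(t) for b in range(a, t)][:t]
    labels = [("cond", p) for p in range(participants)]
    return CouplingTensor(values, mpairs, tpairs, labels, "redundant", 5, t)


class TestMatchAndCorrelate:
    def test_identical_decompositions(self, rng):
        d = _Dec(rng.uniform(0, 1, (10, 3)), rng.uniform(0, 1, (8, 2)))
        rs = match_and_correlate(d, d)
        np.testing.assert_allclose(rs["spatial"], 1.0, atol=1e-12)
        np.testing.assert_allclose(rs["temporal"], 1.0, atol=1e-12)

    def test_permutation_and_scaling_invariance(self, rng):
        sp = rng.uniform(0, 1, (10, 3))
        tp = rng.uniform(0, 1, (8, 2))
        ref = _Dec(sp, tp)
        test = _Dec(3.0 * sp[:, [2, 0, 1]], 0.5 * tp[:, [1, 0]])
        rs = match_and_correlate(ref, test)
        np.testing.assert_allclose(rs["spatial"], 1.0, atol=1e-12)
        np.testing.assert_allclose(rs["temporal"], 1.0, atol=1e-12)

    def test_independent_noise_low_similarity(self, rng):
        rs_all = []
        for _ in range(20):
            ref = _Dec(rng.uniform(0, 1, (36, 3)), rng.uniform(0, 1, (36, 2)))
            test = _Dec(rng.uniform(0, 1, (36, 3)), rng.uniform(0, 1, (36, 2)))
            rs = match_and_correlate(ref, test)
            rs_all.extend(np.abs(rs["spatial"]))
        assert np.mean(rs_all) <= 0.3

    def test_rank_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            match_and_correlate(_Dec(rng.random((10, 3)), rng.random((8, 2))),
                                _Dec(rng.random((10, 2)), rng.random((8, 2))))


class TestFisherSummary:
    def test_zeros_fixed_point(self):
        assert fisher_summary([0.0, 0.0, 0.0]) == (0.0, 0.0)

    def test_single_value(self):
        mean_r, sd_r = fisher_summary([0.7])
        assert mean_r == pytest.approx(0.7, abs=1e-12)
        assert sd_r == 0.0

    def test_direct_formula_oracle(self):
        rs = [0.5, 0.9]
        z = np.arctanh(rs)
        mean_r, sd_r = fisher_summary(rs)
        assert mean_r == pytest.approx(np.tanh(z.mean()), abs=1e-12)
        assert sd_r == pytest.approx(np.tanh(z.std()), abs=1e-12)

    def test_unit_correlations_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            mean_r, _ = fisher_summary([1.0, 0.5])
        assert 0.5 < mean_r < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fisher_summary([])


class TestLeaveNOut:
    def test_duplicated_participants_give_unit_similarity(self, rng):
        tensor = planted_tensor_with_labels(rng, participants=2)
        # duplicate the participant layers so any holdout leaves a copy
        values = np.concatenate([tensor.values, tensor.values], axis=2)
        labels = tensor.layer_labels + [("cond", p + 2) for p in range(2)]
        dup = CouplingTensor(values, tensor.muscle_pairs, tensor.time_pairs,
                            labels, "redundant", 5, tensor.n_timepoints)
        # every holdout leaves a copy of the removed layers, so the
        # information content is unchanged and all matched-factor
        # correlations stay near 1 (up to optimiser tolerance)
        opts = FitOptions(seed=0, n_restarts=6, max_iter=2000, tol=1e-10)
        rep = leave_n_out(dup, (3, 2), axis="participant", opts=opts)
        for row in rep.rows:
            assert row["r"] >= 0.95

    def test_row_count_bookkeeping(self, rng):
        tensor = planted_tensor_with_labels(rng, participants=3)
        opts = FitOptions(seed=0, n_restarts=1, max_iter=100)
        rep = leave_n_out(tensor, (3, 2), axis="participant", opts=opts)
        assert rep.n_iterations == 3
        assert len(rep.rows) == 3 * (3 + 2)  # holdouts x (spatial + temporal factors)

    def test_single_unit_rejected(self, rng):
        tensor = planted_tensor_with_labels(rng, participants=1)
        with pytest.raises(ValidationError):
            leave_n_out(tensor, (3, 2), axis="participant")


class TestRandomAblation:
    def test_zero_fraction_is_noop(self, rng):
        tensor = planted_tensor_with_labels(rng)
        opts = FitOptions(seed=0, n_restarts=2, max_iter=300)
        ref = snm3f_fit(tensor.values, (3, 2), opts)
        rep = random_ablation(tensor, (3, 2), n_iterations=3, seed=1, opts=opts,
                              reference=ref, ablation_fraction=0.0)
        for row in rep.rows:
            assert row["r"] >= 0.999

    def test_iteration_count(self, rng):
        tensor = planted_tensor_with_labels(rng)
        opts = FitOptions(seed=0, n_restarts=1, max_iter=60)
        rep = random_ablation(tensor, (3, 2), n_iterations=5, seed=1, opts=opts)
        assert len({row["unit"] for row in rep.rows}) == 5
        assert len(rep.rows) == 5 * 5

    def test_same_seed_reproduces_report(self, rng):
        tensor = planted_tensor_with_labels(rng)
        opts = FitOptions(seed=0, n_restarts=1, max_iter=60)
        r1 = random_ablation(tensor, (3, 2), n_iterations=3, seed=9, opts=opts)
        r2 = random_ablation(tensor, (3, 2), n_iterations=3, seed=9, opts=opts)
        assert r1.to_records() == r2.to_records()
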