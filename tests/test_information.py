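"""Unit tests for the copula information estimators."""

import numpy as np
import pytest
from scipy.stats import norm

from myotask._exceptions import DegenerateInputError, ValidationError
from myotask.information import (
    TaskVariable,
    cmi,
    co_information,
    copula_normalize,
    gaussian_entropy_bits,
    mi_gc,
    mi_mixed,
    mi_plugin_discrete,
    split_signed,
)
from myotask.synthetic import truth_tables


class TestCopulaNormalize:
    def test_median_maps_to_zero(self):
        out = copula_normalize(np.arange(1, 10, dtype=float))
        assert out[4] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(norm.ppf(1 / 10), abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_allclose(copula_normalize(np.exp(x)), copula_normalize(x))

    def test_ties_match_average_rank_oracle(self):
        x = np.array([3.0, 1.0, 3.0, 2.0, 1.0, 5.0, 2.0, 3.0])
        # brute-force average ranks by sort-and-group
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        pos = 0
        while pos < len(x):
            end = pos
            while end < len(x) and x[order[end]] == x[order[pos]]:
                end += 1
            ranks[order[pos:end]] = (pos + 1 + end) / 2.0
            pos = end
        expected = norm.ppf(ranks / (len(x) + 1))
        np.testing.assert_allclose(copula_normalize(x), expected, atol=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateInputError):
            copula_normalize(np.ones(10))
        with pytest.raises(ValidationError):
            copula_normalize(np.array([1.0, np.nan] + [0.5] * 8))
        with pytest.raises(ValidationError):
            copula_normalize(np.arange(5.0))


class TestGaussianEntropy:
    def test_univariate_closed_form(self, rng):
        h = gaussian_entropy_bits(rng.standard_normal(100_000))
        assert h == pytest.approx(0.5 * np.log2(2 * np.pi * np.e), rel=0.01)

    def test_scaling_law(self, rng):
        x = rng.standard_normal(2000)
        for a in (2.0, 0.25):
            assert gaussian_entropy_bits(a * x) - gaussian_entropy_bits(x) == \
                pytest.approx(np.log2(abs(a)), abs=1e-9)

    def test_bivariate_closed_form(self, rng):
        rho = 0.5
        cov = np.array([[1, rho], [rho, 1]])
        true = 0.5 * np.log2((2 * np.pi * np.e) ** 2 * np.linalg.det(cov))
        draws = [gaussian_entropy_bits(rng.multivariate_normal([0, 0], cov, size=1000))
                 for _ in range(30)]
        # bias-corrected estimator: the mean over repeated draws matches
        assert np.mean(draws) == pytest.approx(true, abs=0.02)

    def test_singular_covariance_rejected(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(DegenerateInputError):
            gaussian_entropy_bits(np.column_stack([x, x]))


class TestMiGc:
    def test_independent_near_zero(self, rng):
        x, y = rng.standard_normal((2, 5000))
        assert mi_gc(x, y).value <= 0.02

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_gaussian_closed_form(self, rho, rng):
        # averaged over draws: at rho=0.3 the closed-form value is ~0.068
        # bits and a single n=1e4 draw has sd ~0.004 bits, so the mean is
        # what meaningfully tests estimator accuracy
        true = -0.5 * np.log2(1 - rho**2)
        draws = []
        for _ in range(15):
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=10_000)
            draws.append(mi_gc(xy[:, 0], xy[:, 1]).value)
        assert np.mean(draws) == pytest.approx(true, rel=0.05)

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.standard_normal((2, 300))
        a = mi_gc(x, y).value
        assert a == mi_gc(y, x).value
        assert a == pytest.approx(mi_gc(np.exp(x), y**3).value, abs=1e-12)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            mi_gc(rng.standard_normal(50), rng.standard_normal(60))


class TestMiMixed:
    def test_shuffled_labels_near_zero(self, rng):
        x = rng.standard_normal(2000)
        tau = TaskVariable("discrete", rng.permutation(np.repeat([0, 1], 1000)))
        assert mi_mixed(x, tau).value <= 0.02

    def test_well_separated_classes_closed_form(self, rng):
        # perfectly separated equiprobable classes: after rank-normalisation
        # the conditionals are half-normals, and the class-conditional
        # Gaussian model yields exactly -0.5*log2(1 - 2/pi) bits
        lab = np.repeat([0, 1], 1000)
        x = np.where(lab == 0, -10.0, 10.0) + rng.standard_normal(2000)
        expected = -0.5 * np.log2(1 - 2 / np.pi)
        assert mi_mixed(x, TaskVariable("discrete", lab)).value == \
            pytest.approx(expected, rel=0.05)

    def test_monotone_invariance(self, rng):
        lab = np.repeat([0, 1, 2], 200)
        x = lab + rng.standard_normal(600)
        tau = TaskVariable("discrete", lab)
        assert mi_mixed(x, tau).value == pytest.approx(
            mi_mixed(np.exp(x), tau).value, abs=1e-12)

    def test_undersized_class_named_in_error(self, rng):
        lab = np.array(["a"] * 50 + ["b"] * 2)
        tau = TaskVariable("discrete", lab)
        with pytest.raises(DegenerateInputError, match="'b'"):
            mi_mixed(rng.standard_normal(52), tau)


class TestCmi:
    def test_conditional_independence(self, rng):
        n = 5000
        lab = rng.integers(0, 2, n)
        x = lab + 0.5 * rng.standard_normal(n)
        y = -lab.astype(float) + 0.5 * rng.standard_normal(n)
        assert cmi(x, y, TaskVariable("discrete", lab)).value <= 0.05

    def test_shared_latent_analytic(self, rng):
        n = 5000
        lab = rng.integers(0, 2, n)
        z = rng.standard_normal(n)
        x = z + 0.5 * rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        rho = 1.0 / 1.25
        true = -0.5 * np.log2(1 - rho**2)
        assert cmi(x, y, TaskVariable("discrete", lab)).value == \
            pytest.approx(true, rel=0.10)

    def test_continuous_conditioning_removes_shared_driver(self, rng):
        n = 4000
        z = rng.standard_normal(n)
        x = z + 0.3 * rng.standard_normal(n)
        y = z + 0.3 * rng.standard_normal(n)
        raw = mi_gc(x, y).value
        conditioned = cmi(x, y, z).value
        assert conditioned < 0.2 * raw

    def test_symmetry(self, rng):
        n = 500
        lab = rng.integers(0, 2, n)
        x, y = rng.standard_normal((2, n))
        tau = TaskVariable("discrete", lab)
        assert cmi(x, y, tau).value == pytest.approx(cmi(y, x, tau).value, abs=1e-12)


class TestCoInformation:
    def test_redundancy_table_minus_one_bit(self):
        red, _ = truth_tables()
        est = co_information(red["mx"], red["my"], red["tau"],
                             estimator="plugin_discrete")
        assert est.value == pytest.approx(-1.0, abs=1e-12)

    def test_synergy_table_plus_one_bit(self):
        _, syn = truth_tables()
        est = co_information(syn["mx"], syn["my"], syn["tau"],
                             estimator="plugin_discrete")
        assert est.value == pytest.approx(1.0, abs=1e-12)
        assert est.components["mi_x"] == pytest.approx(0.0, abs=1e-12)
        assert est.components["mi_y"] == pytest.approx(0.0, abs=1e-12)

    def test_mutual_independence_near_zero(self, rng):
        x, y = rng.standard_normal((2, 5000))
        lab = rng.integers(0, 2, 5000)
        est = co_information(x, y, TaskVariable("discrete", lab))
        assert abs(est.value) <= 0.05

    @pytest.mark.parametrize("kind", ["discrete", "continuous"])
    def test_additive_identity_exact_per_call(self, kind, rng):
        n = 400
        x, y = rng.standard_normal((2, n))
        if kind == "discrete":
            tau = TaskVariable("discrete", rng.integers(0, 3, n))
        else:
            tau = rng.standard_normal(n)
        est = co_information(x, y, tau)
        c = est.components
        assert est.value == c["mi_joint"] - c["mi_x"] - c["mi_y"]


class TestPluginDiscrete:
    def test_identity_binary(self):
        x = np.tile([0, 1], 20)
        assert mi_plugin_discrete(x, x).value == pytest.approx(1.0, abs=1e-12)

    def test_three_symbol_joint_matches_direct_summation(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 3, 200)
        joint = np.zeros((3, 3))
        np.add.at(joint, (x, y), 1.0)
        p = joint / 200
        px, py = p.sum(1), p.sum(0)
        expected = sum(p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
                       for i in range(3) for j in range(3) if p[i, j] > 0)
        assert mi_plugin_discrete(x, y).value == pytest.approx(max(0.0, expected),
                                                               abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mi_plugin_discrete(np.array([]), np.array([]))


class TestSplitSigned:
    def test_rectified_halves(self):
        m = np.array([[0.0, -0.3], [-0.3, 0.0]])
        red, syn = split_signed(m)
        np.testing.assert_allclose(red, [[0, 0.3], [0.3, 0]])
        np.testing.assert_allclose(syn, 0.0)
        red, syn = split_signed(-m)
        np.testing.assert_allclose(syn, [[0, 0.3], [0.3, 0]])
        np.testing.assert_allclose(red, 0.0)

    def test_reconstruction_identity(self, rng):
        m = rng.standard_normal((6, 6))
        m = m + m.T
        red, syn = split_signed(m)
        np.testing.assert_allclose(syn - red, m, atol=1e-15)
        assert (red >= 0).all() and (syn >= 0).all()

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValidationError):
            split_signed(rng.standard_normal((4, 4)))
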