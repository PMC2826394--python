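"""Nonparametric entropy estimators against closed forms and a
brute-force reference implementation."""

import math

import numpy as np
import pytest

from mcsa_entropy import (EstimationError, EstimatorConfig, ParameterError,
                          adaptive_kernel_entropy, knn_entropy,
                          marginal_entropy_1d, unit_ball_volume)

from conftest import brute_force_knn_entropy

LN_2PIE = math.log(2 * math.pi * math.e)
H_UNIT_GAUSS = 0.5 * LN_2PIE  # 1.41894 nats


@pytest.mark.parametrize("d,expected", [(1, 2.0), (2, math.pi),
                                        (3, 4 * math.pi / 3)])
def test_unit_ball_volume(d, expected):
    assert unit_ball_volume(d) == pytest.approx(expected, rel=1e-12)


def test_unit_ball_volume_invalid():
    with pytest.raises(ParameterError):
        unit_ball_volume(0)


class TestKnn:
    def test_two_point_hand_case(self):
        """n=2, d=1, points {0,1}, k=1: ψ(2)−ψ(1)+ln2 = 1 + ln 2."""
        est = knn_entropy(np.array([[0.0], [1.0]]), k=1, stderr_blocks=0)
        assert est.value == pytest.approx(1.0 + math.log(2.0), abs=1e-12)
        assert est.value == pytest.approx(
            brute_force_knn_entropy([[0.0], [1.0]], 1), abs=0)

    @pytest.mark.parametrize("d,k,seed", [(1, 1, 0), (2, 5, 1), (7, 3, 2)])
    def test_equals_brute_force_exactly(self, d, k, seed):
        X = np.random.default_rng(seed).standard_normal((150, d))
        est = knn_entropy(X, k=k, stderr_blocks=0)
        assert est.value == brute_force_knn_entropy(X, k)

    def test_gaussian_1d(self):
        X = np.random.default_rng(10).standard_normal((20_000, 1))
        assert knn_entropy(X, k=5).value == pytest.approx(H_UNIT_GAUSS,
                                                          abs=0.02)

    def test_uniform_square(self):
        X = np.random.default_rng(11).random((10_000, 2))
        assert knn_entropy(X, k=5).value == pytest.approx(0.0, abs=0.05)

    def test_duplicates_fail_with_message(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]] * 5)
        with pytest.raises(EstimationError, match="jitter"):
            knn_entropy(X, k=1, stderr_blocks=0)
        # opt-in deterministic jitter resolves it reproducibly
        a = knn_entropy(X, k=1, jitter_duplicates=True, stderr_blocks=0)
        b = knn_entropy(X, k=1, jitter_duplicates=True, stderr_blocks=0)
        assert a.value == b.value and np.isfinite(a.value)

    def test_k_out_of_range(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ParameterError):
            knn_entropy(X, k=10)


class TestAdaptiveKernel:
    def test_identity_shape_reduces_to_knn_bitwise(self):
        X = np.random.default_rng(1).standard_normal((3000, 4))
        iso = adaptive_kernel_entropy(
            X, EstimatorConfig(identity_shape=True, stderr_blocks=0))
        ref = knn_entropy(X, k=5, stderr_blocks=0)
        assert iso.value == ref.value

    def test_anisotropic_2d_beats_knn(self):
        """diag(1, 0.01) gaussian: the ellipsoidal kernel must be within
        2% of closed form and no more biased than plain k-NN (paired
        over 10 seeds)."""
        true = 0.5 * math.log((2 * math.pi * math.e) ** 2 * 0.01)
        errs_a, errs_k = [], []
        for seed in range(10):
            X = np.random.default_rng(seed).standard_normal((20_000, 2)) \
                * np.array([1.0, 0.1])
            errs_a.append(adaptive_kernel_entropy(
                X, EstimatorConfig(stderr_blocks=0)).value - true)
            errs_k.append(knn_entropy(X, stderr_blocks=0).value - true)
        bias_a, bias_k = np.mean(errs_a), np.mean(errs_k)
        assert abs(bias_a) <= abs(true) * 0.02
        assert abs(bias_a) <= abs(bias_k)

    def test_local_k_validation(self):
        X = np.random.default_rng(0).standard_normal((500, 4))
        with pytest.raises(ParameterError):
            adaptive_kernel_entropy(X, EstimatorConfig(local_k=3))


class TestMarginal1d:
    def test_gaussian(self):
        x = np.random.default_rng(3).standard_normal(50_000)
        assert marginal_entropy_1d(x).value == pytest.approx(H_UNIT_GAUSS,
                                                             abs=0.01)

    def test_uniform(self):
        x = np.random.default_rng(4).random(50_000)
        assert marginal_entropy_1d(x).value == pytest.approx(0.0, abs=0.01)

    def test_scaling_law(self):
        x = np.random.default_rng(5).standard_normal(50_000)
        h1 = marginal_entropy_1d(x).value
        h2 = marginal_entropy_1d(2.0 * x).value
        assert h2 - h1 == pytest.approx(math.log(2.0), abs=0.01)

    def test_histogram_method(self):
        x = np.random.default_rng(6).standard_normal(50_000)
        assert marginal_entropy_1d(x, method="histogram").value \
            == pytest.approx(H_UNIT_GAUSS, abs=0.02)

    def test_constant_column(self):
        with pytest.raises(EstimationError):
            marginal_entropy_1d(np.ones(100))

    def test_matches_full_knn_estimator(self):
        """The O(n log n) sorted-window path must agree with the generic
        k-NN estimator run on the same column."""
        x = np.random.default_rng(7).standard_normal(1500)
        a = marginal_entropy_1d(x, k=5).value
        b = knn_entropy(x[:, None], k=5, stderr_blocks=0).value
        assert a == pytest.approx(b, abs=1e-12)


class TestInvariances:
    def test_translation(self):
        X = np.random.default_rng(8).standard_normal((2000, 3))
        a = knn_entropy(X, stderr_blocks=0).value
        b = knn_entropy(X + 17.3, stderr_blocks=0).value
        assert abs(a - b) < 1e-9

    def test_scaling(self):
        X = np.random.default_rng(9).standard_normal((5000, 3))
        a = knn_entropy(X, stderr_blocks=0).value
        b = knn_entropy(2.5 * X, stderr_blocks=0).value
        assert b - a == pytest.approx(3 * math.log(2.5), abs=0.03)

    def test_orthonormal_transform(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20_000, 5))
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        a = adaptive_kernel_entropy(X, EstimatorConfig())
        b = adaptive_kernel_entropy(X @ Q.T, EstimatorConfig())
        tol = 3 * math.hypot(a.stderr, b.stderr)
        assert abs(a.value - b.value) <= tol

    def test_consistency_bias_shrinks_with_n(self):
        true = 3 * H_UNIT_GAUSS
        biases = []
        for n in (500, 5_000, 50_000):
            errs = [knn_entropy(np.random.default_rng(100 * n + s)
                                .standard_normal((n, 3)),
                                stderr_blocks=0).value - true
                    for s in range(10)]
            biases.append(abs(np.mean(errs)))
        assert biases[0] > biases[1] > biases[2] or biases[2] < 0.005
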