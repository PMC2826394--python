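"""Mutual information expansion: coefficients, fill modes, estimates."""

import math
from itertools import combinations

import numpy as np
import pytest

from mcsa_entropy import (EstimatorConfig, ParameterError, SyntheticSpec,
                          cluster_entropy, correlation_matrix,
                          derive_coefficients, fill_block, gaussian_entropy,
                          mie_entropy, mutual_information_pair, sample,
                          threshold_cluster, subdivide_oversized)


def symbolic_mie_coefficients(K, M):
    """Independent oracle: expand Σ_m (−1)^{m+1} Σ_{|T|=m} I_m(T) term by
    term over explicit subsets and collect the multiplier of each
    entropy term S(U); verify all same-size subsets agree."""
    from collections import defaultdict

    weight = defaultdict(int)
    for m in range(1, M + 1):
        outer = (-1) ** (m + 1)
        for T in combinations(range(K), m):
            # I_m(T) = -Σ_{∅≠U⊆T} (−1)^{|U|} S(U)
            for u in range(1, m + 1):
                for U in combinations(T, u):
                    weight[U] += outer * (-(-1) ** u)
    by_size = {}
    for U, w in weight.items():
        by_size.setdefault(len(U), set()).add(w)
    assert all(len(ws) == 1 for ws in by_size.values())
    return {u: ws.pop() for u, ws in by_size.items()}


class TestCoefficients:
    @pytest.mark.parametrize("K", range(2, 7))
    @pytest.mark.parametrize("M", (2, 3))
    def test_matches_symbolic_expansion(self, K, M):
        if M > K:
            pytest.skip("M must be <= K")
        assert derive_coefficients(K, M) == symbolic_mie_coefficients(K, M)

    def test_known_values(self):
        assert derive_coefficients(3, 2) == {1: -1, 2: 1}
        assert derive_coefficients(4, 2) == {1: -2, 2: 1}
        assert derive_coefficients(3, 3) == {1: 0, 2: 0, 3: 1}

    def test_invalid_order(self):
        with pytest.raises(ParameterError):
            derive_coefficients(2, 3)
        with pytest.raises(ParameterError):
            derive_coefficients(3, 4)


class TestFillBlock:
    def test_marginals_preserved(self):
        X = np.random.default_rng(0).standard_normal((500, 4))
        F = fill_block(X, [1, 2], seed=5)
        for c in range(2):
            np.testing.assert_array_equal(np.sort(F[:, c]),
                                          np.sort(X[:, c + 1]))

    def test_joint_permutation_keeps_intra_block_structure(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1000)
        X = np.column_stack([a, a, rng.standard_normal(1000)])
        F = fill_block(X, [0, 1], seed=2)
        assert np.corrcoef(F[:, 0], F[:, 1])[0, 1] == pytest.approx(1.0)

    def test_decorrelates_from_original(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        y = x + 0.1 * rng.standard_normal(10_000)   # strongly dependent
        F = fill_block(np.column_stack([x, y]), [1], seed=3)
        assert mutual_information_pair(x, F[:, 0], seed=4) < 0.02

    def test_empty_block(self):
        with pytest.raises(ParameterError):
            fill_block(np.zeros((10, 2)), [], seed=0)


class TestMieEntropy:
    def test_independent_blocks_exact(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.7
        S[2, 3] = S[3, 2] = -0.5
        spec = SyntheticSpec(kind="gaussian", n=20_000, seed=3,
                             params={"cov": S.tolist()})
        est, rec = mie_entropy(sample(spec), [[0, 1], [2, 3]], 2,
                               EstimatorConfig(), seed=4)
        assert est.value == pytest.approx(gaussian_entropy(S),
                                          abs=3 * est.stderr)
        for t in rec.joint_entropies.values():
            assert t["filled_dim"] == rec.plan.target_dim == 4

    def test_three_modes_full_order_exact(self):
        A = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        spec = SyntheticSpec(kind="gaussian", n=20_000, seed=5,
                             params={"cov": A.tolist()})
        est, _ = mie_entropy(sample(spec), [[0], [1], [2]], 3,
                             EstimatorConfig(), seed=6)
        assert est.value == pytest.approx(gaussian_entropy(A),
                                          abs=3 * est.stderr + 0.02)

    def test_mie2_below_mie3_for_coupled_gaussian(self):
        """Pairwise-correlated gaussian: across seeds the 2nd-order
        estimate stays at or below the exact 3rd-order one."""
        A = np.array([[1.0, 0.6, 0.6], [0.6, 1.0, 0.6], [0.6, 0.6, 1.0]])
        lower = 0
        for seed in range(10):
            spec = SyntheticSpec(kind="gaussian", n=10_000, seed=seed,
                                 params={"cov": A.tolist()})
            X = sample(spec)
            m2, _ = mie_entropy(X, [[0], [1], [2]], 2,
                                EstimatorConfig(stderr_blocks=0), seed=seed)
            m3, _ = mie_entropy(X, [[0], [1], [2]], 3,
                                EstimatorConfig(stderr_blocks=0), seed=seed)
            lower += m2.value <= m3.value + 0.02
        assert lower >= 9

    def test_unequal_subcluster_sizes_consistent(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((5, 5)) * 0.2
        S = A @ A.T + np.eye(5)
        spec = SyntheticSpec(kind="gaussian", n=15_000, seed=8,
                             params={"cov": S.tolist()})
        X = sample(spec)
        est, rec = mie_entropy(X, [[0, 1, 2], [3, 4]], 2,
                               EstimatorConfig(), seed=9)
        assert rec.plan.target_dim == 5
        assert est.value == pytest.approx(gaussian_entropy(S),
                                          abs=3 * est.stderr + 0.05)
        est3, _ = mie_entropy(X, [[0, 1], [2], [3, 4]], 3,
                              EstimatorConfig(), seed=10)
        assert est3.value == pytest.approx(gaussian_entropy(S),
                                           abs=3 * est3.stderr + 0.05)

    def test_fill_seed_robustness(self):
        spec = SyntheticSpec(kind="block_gaussian", n=20_000, seed=11,
                             params={"block_sizes": [2, 2], "rho": 0.5})
        X = sample(spec)
        a, _ = mie_entropy(X, [[0, 1], [2, 3]], 2, EstimatorConfig(), seed=1)
        b, _ = mie_entropy(X, [[0, 1], [2, 3]], 2, EstimatorConfig(), seed=2)
        assert abs(a.value - b.value) <= 3 * math.hypot(a.stderr, b.stderr)

    def test_dimension_cap_refused(self):
        X = np.random.default_rng(12).standard_normal((2000, 6))
        with pytest.raises(ParameterError, match="cap"):
            mie_entropy(X, [[0, 1, 2], [3, 4, 5]], 2, EstimatorConfig(),
                        seed=0, max_dim=5)

    def test_k_less_than_m(self):
        X = np.random.default_rng(13).standard_normal((2000, 2))
        with pytest.raises(ParameterError):
            mie_entropy(X, [[0], [1]], 3, EstimatorConfig(), seed=0)


class TestClusterEntropy:
    def _partitioned(self, spec, r_c, s_max):
        X = sample(spec)
        R = correlation_matrix(X, seed=0)
        p = threshold_cluster(R, r_c)
        return X, subdivide_oversized(p, R, s_max)

    def test_small_clusters_all_direct(self):
        spec = SyntheticSpec(kind="block_gaussian", n=8_000, seed=14,
                             params={"block_sizes": [2, 2], "rho": 0.6})
        X, p = self._partitioned(spec, 0.3, 5)
        out = cluster_entropy(X, p, EstimatorConfig(), M=2, seed=0)
        assert all(c["method"] == "direct" for c in out)
        from mcsa_entropy import exact_covariance
        total = sum(c["estimate"].value for c in out)
        assert total == pytest.approx(
            gaussian_entropy(exact_covariance(spec)), abs=0.1)

    def test_oversized_cluster_uses_mie(self):
        spec = SyntheticSpec(kind="block_gaussian", n=10_000, seed=15,
                             params={"block_sizes": [6], "rho": 0.5})
        X, p = self._partitioned(spec, 0.3, 3)
        out = cluster_entropy(X, p, EstimatorConfig(), M=2, seed=0)
        assert out[0]["method"] == "mie2"
        from mcsa_entropy import exact_covariance
        est = out[0]["estimate"]
        assert est.value == pytest.approx(
            gaussian_entropy(exact_covariance(spec)), abs=3 * est.stderr + 0.1)
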