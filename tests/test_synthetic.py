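"""Synthetic generators and their independent entropy oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mcsa_entropy import (OracleError, ParameterError, SyntheticSpec,
                          exact_covariance, gaussian_entropy, log_density,
                          oracle_entropy, qh_gap, sample)

LN_2PIE = math.log(2 * math.pi * math.e)


def test_sampling_matches_requested_covariance():
    spec = SyntheticSpec(kind="gaussian", n=1000, seed=7,
                         params={"cov": np.eye(3).tolist()})
    X = sample(spec).X
    assert X.shape == (1000, 3)
    C = np.cov(X, rowvar=False)
    assert np.abs(C - np.eye(3)).max() < 0.15


def test_sampling_deterministic():
    spec = SyntheticSpec(kind="double_well_chain", n=500, seed=3,
                         params={"d": 4})
    np.testing.assert_array_equal(sample(spec).X, sample(spec).X)


@pytest.mark.parametrize("bad", [
    {"kind": "gaussian_mixture", "params": {"means": [[-1], [1]],
                                            "weights": [0.5, 0.6]}},
    {"kind": "gaussian", "params": {"cov": [[1.0, 2.0], [2.0, 1.0]]}},
    {"kind": "rotated_uniforms", "params": {"widths": [1.0, -1.0]}},
])
def test_invalid_params_rejected(bad):
    with pytest.raises(ParameterError):
        SyntheticSpec(kind=bad["kind"], n=100, seed=0, params=bad["params"])


class TestOracles:
    def test_unit_gaussian_1d(self):
        spec = SyntheticSpec(kind="gaussian", n=10, seed=0,
                             params={"cov": [[1.0]]})
        o = oracle_entropy(spec)
        assert o.error == 0.0
        assert o.value == pytest.approx(0.5 * LN_2PIE, abs=1e-12)

    def test_rotated_uniform_unit_square_is_zero(self):
        spec = SyntheticSpec(kind="rotated_uniforms", n=10, seed=0,
                             params={"widths": [1.0, 1.0], "angle_deg": 33.0})
        assert oracle_entropy(spec).value == pytest.approx(0.0, abs=1e-12)

    def test_two_component_mixture_quadrature(self):
        """Well-separated ±3 mixture: H ≈ ½ln(2πe) + ln 2, cross-checked
        against an independent 1-D quadrature done here."""
        spec = SyntheticSpec(kind="gaussian_mixture", n=10, seed=0,
                             params={"means": [[-3.0], [3.0]],
                                     "weights": [0.5, 0.5]})
        o = oracle_entropy(spec)

        def p(x):
            return 0.5 / math.sqrt(2 * math.pi) * (
                math.exp(-0.5 * (x - 3) ** 2) + math.exp(-0.5 * (x + 3) ** 2))

        ref, _ = quad(lambda x: -p(x) * math.log(p(x)), -15, 15, limit=300)
        assert o.value == pytest.approx(ref, abs=1e-4)
        # infinite-separation asymptote ½ln(2πe)+ln2; ±3 wells overlap a bit
        assert o.value == pytest.approx(0.5 * LN_2PIE + math.log(2), abs=5e-3)

    def test_resubstitution_agrees_with_closed_form(self):
        for d in (1, 5, 20):
            rng = np.random.default_rng(d)
            A = rng.standard_normal((d, d)) * 0.3
            cov = A @ A.T + np.eye(d)
            spec = SyntheticSpec(kind="gaussian", n=10, seed=d,
                                 params={"cov": cov.tolist()})
            mc = oracle_entropy(spec, method="monte_carlo_resubstitution",
                                n_mc=50_000)
            closed = gaussian_entropy(cov)
            assert abs(mc.value - closed) < 3 * mc.error + 1e-9

    def test_chain_quadrature_vs_resubstitution(self):
        spec = SyntheticSpec(kind="double_well_chain", n=10, seed=1,
                             params={"d": 6})
        q = oracle_entropy(spec, method="quadrature")
        mc = oracle_entropy(spec, method="monte_carlo_resubstitution",
                            n_mc=100_000)
        assert abs(q.value - mc.value) < 3 * mc.error + 1e-6

    def test_unsupported_combination_raises(self):
        spec = SyntheticSpec(kind="gaussian_mixture", n=10, seed=0,
                             params={"means": np.zeros((2, 5)).tolist()})
        with pytest.raises(OracleError):
            oracle_entropy(spec, method="quadrature")

    def test_rotation_invariance(self):
        base = SyntheticSpec(kind="rotated_uniforms", n=10, seed=0,
                             params={"widths": [2.0, 0.5], "angle_deg": 0.0})
        rot = SyntheticSpec(kind="rotated_uniforms", n=10, seed=0,
                            params={"widths": [2.0, 0.5], "angle_deg": 71.0})
        assert oracle_entropy(base).value == pytest.approx(
            oracle_entropy(rot).value, abs=1e-12)
        cov = np.diag([1.0, 4.0])
        th = math.radians(30)
        Q = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        g1 = SyntheticSpec(kind="gaussian", n=10, seed=0,
                           params={"cov": cov.tolist()})
        g2 = SyntheticSpec(kind="gaussian", n=10, seed=0,
                           params={"cov": (Q @ cov @ Q.T).tolist()})
        assert oracle_entropy(g1).value == pytest.approx(
            oracle_entropy(g2).value, abs=1e-10)


class TestQhGap:
    def test_zero_for_pure_gaussian(self):
        spec = SyntheticSpec(kind="gaussian", n=10, seed=0,
                             params={"cov": [[2.0, 0.3], [0.3, 1.0]]})
        assert qh_gap(spec) == pytest.approx(0.0, abs=1e-10)

    def test_mixture_gap_positive_and_exact(self):
        spec = SyntheticSpec(kind="gaussian_mixture", n=10, seed=0,
                             params={"means": [[-3.0], [3.0]],
                                     "weights": [0.5, 0.5]})
        # exact covariance of the mixture is 1 + a² = 10
        assert exact_covariance(spec)[0, 0] == pytest.approx(10.0)
        gap = qh_gap(spec)
        expected = 0.5 * math.log(2 * math.pi * math.e * 10.0) \
            - oracle_entropy(spec).value
        assert gap == pytest.approx(expected, abs=1e-9)
        assert gap > 0.3

    def test_rotated_uniforms_gap(self):
        spec = SyntheticSpec(kind="rotated_uniforms", n=10, seed=0,
                             params={"widths": [1.0, 1.0], "angle_deg": 10.0})
        # QH sees variance 1/12 per axis; the true entropy is 0, so the
        # gap is ½ln((2πe)²/12²) = ln(2πe/12) ≈ 0.3530 nats
        expected = 2 * 0.5 * math.log(2 * math.pi * math.e / 12.0)
        assert qh_gap(spec) == pytest.approx(expected, abs=1e-9)
        assert qh_gap(spec) == pytest.approx(0.3530, abs=2e-4)


def test_chain_exact_covariance_matches_samples():
    spec = SyntheticSpec(kind="double_well_chain", n=100_000, seed=9,
                         params={"d": 5})
    S = exact_covariance(spec)
    C = np.cov(sample(spec).X, rowvar=False)
    assert np.abs(C - S).max() / S.max() < 0.05


def test_log_density_normalised_1d():
    spec = SyntheticSpec(kind="gaussian_mixture", n=10, seed=0,
                         params={"means": [[-1.0], [2.0]],
                                 "weights": [0.3, 0.7]})
    xs = np.linspace(-12, 12, 4001)[:, None]
    p = np.exp(log_density(spec, xs))
    assert np.trapezoid(p.ravel(), xs.ravel()) == pytest.approx(1.0, abs=1e-6)
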