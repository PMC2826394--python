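"""Synthetic ensembles with known entropies.

These distributions emulate, at desk scale, the statistical features a
configurational-entropy estimator must face in molecular ensembles:

* ``gaussian`` / ``block_gaussian`` — the quasi-harmonic regime and
  block-correlated mode structure,
* ``rotated_uniforms`` — bounded, strongly non-Gaussian independent
  sources mixed by an orthonormal rotation (the unmixing target of full
  correlation analysis),
* ``gaussian_mixture`` — multi-minima densities for which a Gaussian
  fit overestimates the entropy,
* ``double_well_chain`` — a chain of coupled coordinates whose first
  coordinate hops between two wells and whose successors are
  conditionally Gaussian given their predecessor; a tractable stand-in
  for correlated multi-minima dihedral dynamics.

Every kind provides an independent reference entropy (`oracle_entropy`):
closed form where available, deterministic quadrature for mixtures (the
chain's conditional structure reduces any dimension to one 1-D
integral), and Monte-Carlo resubstitution (−mean log true density over
fresh draws) as the general fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
from scipy.integrate import quad, nquad
from scipy.special import logsumexp

from .ensemble_io import SampleMatrix
from .exceptions import OracleError, ParameterError

_LN_2PIE = math.log(2.0 * math.pi * math.e)


class Kind(str, Enum):
    GAUSSIAN = "gaussian"
    GAUSSIAN_MIXTURE = "gaussian_mixture"
    ROTATED_UNIFORMS = "rotated_uniforms"
    DOUBLE_WELL_CHAIN = "double_well_chain"
    BLOCK_GAUSSIAN = "block_gaussian"


class OracleMethod(str, Enum):
    CLOSED_FORM = "closed_form"
    QUADRATURE = "quadrature"
    MONTE_CARLO = "monte_carlo_resubstitution"


@dataclass
class SyntheticSpec:
    kind: Kind
    n: int
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.kind = Kind(self.kind)
        if self.n < 2:
            raise ParameterError(f"need n >= 2 samples, got {self.n}")
        _validate(self)

    def to_dict(self) -> dict:
        p = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.params.items()}
        return {"kind": self.kind.value, "n": self.n, "seed": self.seed,
                "params": p}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(kind=Kind(d["kind"]), n=int(d["n"]),
                   seed=int(d.get("seed", 0)), params=dict(d.get("params", {})))


@dataclass
class OracleEntropy:
    value: float            # nats
    method: OracleMethod
    error: float = 0.0      # standard error, 0 for closed form

    def __post_init__(self):
        if self.error < 0:
            raise ParameterError("oracle error must be >= 0")


# ---------------------------------------------------------------------------
# parameter handling
# ---------------------------------------------------------------------------

def _check_spd(S: np.ndarray, what: str) -> np.ndarray:
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ParameterError(f"{what} must be a symmetric matrix")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ParameterError(f"{what} must be positive definite") from None
    return S


def _validate(spec: SyntheticSpec) -> None:
    p = spec.params
    if spec.kind is Kind.GAUSSIAN:
        _check_spd(p.get("cov", [[1.0]]), "covariance")
    elif spec.kind is Kind.GAUSSIAN_MIXTURE:
        w = np.asarray(p.get("weights", [0.5, 0.5]), dtype=np.float64)
        if w.min() <= 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("mixture weights must be positive and sum to 1")
        for c in _mixture_covs(spec):
            _check_spd(c, "component covariance")
    elif spec.kind is Kind.BLOCK_GAUSSIAN:
        _check_spd(_block_cov(spec), "block covariance")
    elif spec.kind is Kind.ROTATED_UNIFORMS:
        if np.any(np.asarray(_widths(spec)) <= 0):
            raise ParameterError("uniform widths must be positive")
    elif spec.kind is Kind.DOUBLE_WELL_CHAIN:
        for key, v in (("sigma", p.get("sigma", 0.5)),
                       ("tau", p.get("tau", 0.5))):
            if v <= 0:
                raise ParameterError(f"{key} must be positive")


def _mixture_means(spec) -> np.ndarray:
    return np.atleast_2d(np.asarray(
        spec.params.get("means", [[-3.0], [3.0]]), dtype=np.float64))


def _mixture_covs(spec) -> np.ndarray:
    means = _mixture_means(spec)
    c, d = means.shape
    covs = spec.params.get("covs")
    if covs is None:
        covs = np.tile(np.eye(d), (c, 1, 1))
    covs = np.asarray(covs, dtype=np.float64)
    if covs.ndim == 2:
        covs = np.tile(covs, (c, 1, 1))
    return covs


def _mixture_weights(spec) -> np.ndarray:
    return np.asarray(spec.params.get(
        "weights", np.full(len(_mixture_means(spec)), 1.0 / len(_mixture_means(spec)))),
        dtype=np.float64)


def _widths(spec) -> np.ndarray:
    return np.asarray(np.atleast_1d(spec.params.get("widths", [1.0, 1.0])),
                      dtype=np.float64)


def _rotation(spec) -> np.ndarray:
    d = _widths(spec).size
    if "angle_deg" in spec.params:
        if d != 2:
            raise ParameterError("angle_deg rotation applies to d=2 only")
        t = math.radians(float(spec.params["angle_deg"]))
        return np.array([[math.cos(t), -math.sin(t)],
                         [math.sin(t), math.cos(t)]])
    if "rotation" in spec.params:
        Q = np.asarray(spec.params["rotation"], dtype=np.float64)
        if not np.allclose(Q @ Q.T, np.eye(d), atol=1e-8):
            raise ParameterError("rotation must be orthonormal")
        return Q
    rs = int(spec.params.get("rotation_seed", 0))
    G = np.random.default_rng(rs).standard_normal((d, d))
    Q, R = np.linalg.qr(G)
    return Q * np.sign(np.diag(R))


def _chain_params(spec) -> tuple[int, float, float, float, float]:
    p = spec.params
    return (int(p.get("d", 12)), float(p.get("separation", 1.5)),
            float(p.get("sigma", 0.5)), float(p.get("coupling", 0.8)),
            float(p.get("tau", 0.5)))


def _block_cov(spec) -> np.ndarray:
    p = spec.params
    sizes = list(p.get("block_sizes", [5, 5, 5]))
    rho = p.get("rho", 0.5)
    rhos = [rho] * len(sizes) if np.isscalar(rho) else list(rho)
    var = float(p.get("variance", 1.0))
    blocks = []
    for s, r in zip(sizes, rhos):
        B = np.full((s, s), r, dtype=np.float64)
        np.fill_diagonal(B, 1.0)
        blocks.append(B * var)
    d = sum(sizes)
    S = np.zeros((d, d))
    o = 0
    for B in blocks:
        s = B.shape[0]
        S[o:o + s, o:o + s] = B
        o += s
    return S


def exact_covariance(spec: SyntheticSpec) -> np.ndarray:
    """Closed-form covariance of the specified density."""
    if spec.kind is Kind.GAUSSIAN:
        return _check_spd(spec.params.get("cov", [[1.0]]), "covariance")
    if spec.kind is Kind.BLOCK_GAUSSIAN:
        return _block_cov(spec)
    if spec.kind is Kind.ROTATED_UNIFORMS:
        Q = _rotation(spec)
        return Q @ np.diag(_widths(spec) ** 2 / 12.0) @ Q.T
    if spec.kind is Kind.GAUSSIAN_MIXTURE:
        means, covs, w = _mixture_means(spec), _mixture_covs(spec), _mixture_weights(spec)
        mu = w @ means
        S = sum(wi * (Ci + np.outer(mi, mi)) for wi, mi, Ci in zip(w, means, covs))
        return S - np.outer(mu, mu)
    if spec.kind is Kind.DOUBLE_WELL_CHAIN:
        d, a, sigma, c, tau = _chain_params(spec)
        v = np.empty(d)
        v[0] = a * a + sigma * sigma
        for j in range(1, d):
            v[j] = c * c * v[j - 1] + tau * tau
        S = np.empty((d, d))
        for i in range(d):
            for j in range(i, d):
                S[i, j] = S[j, i] = c ** (j - i) * v[i]
        return S
    raise OracleError(f"no covariance for kind {spec.kind}")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(spec: SyntheticSpec) -> SampleMatrix:
    """Draw spec.n i.i.d. rows; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    k = spec.kind
    if k in (Kind.GAUSSIAN, Kind.BLOCK_GAUSSIAN):
        S = exact_covariance(spec)
        L = np.linalg.cholesky(S)
        X = rng.standard_normal((spec.n, S.shape[0])) @ L.T
        if k is Kind.GAUSSIAN and "mean" in spec.params:
            X = X + np.asarray(spec.params["mean"], dtype=np.float64)
    elif k is Kind.ROTATED_UNIFORMS:
        w = _widths(spec)
        U = (rng.random((spec.n, w.size)) - 0.5) * w
        X = U @ _rotation(spec).T
    elif k is Kind.GAUSSIAN_MIXTURE:
        means, covs, wts = _mixture_means(spec), _mixture_covs(spec), _mixture_weights(spec)
        comp = rng.choice(len(wts), size=spec.n, p=wts)
        X = np.empty((spec.n, means.shape[1]))
        for c in range(len(wts)):
            m = comp == c
            if m.any():
                L = np.linalg.cholesky(covs[c])
                X[m] = rng.standard_normal((int(m.sum()), means.shape[1])) @ L.T + means[c]
    elif k is Kind.DOUBLE_WELL_CHAIN:
        d, a, sigma, c, tau = _chain_params(spec)
        X = np.empty((spec.n, d))
        signs = rng.choice([-1.0, 1.0], size=spec.n)
        X[:, 0] = signs * a + rng.standard_normal(spec.n) * sigma
        for j in range(1, d):
            X[:, j] = c * X[:, j - 1] + rng.standard_normal(spec.n) * tau
    else:  # pragma: no cover
        raise ParameterError(f"unknown kind {k}")
    return SampleMatrix(X=X, weighting="plain")


def log_density(spec: SyntheticSpec, X: np.ndarray) -> np.ndarray:
    """Exact log density of the spec at rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    k = spec.kind
    if k in (Kind.GAUSSIAN, Kind.BLOCK_GAUSSIAN):
        S = exact_covariance(spec)
        mu = np.asarray(spec.params.get("mean", np.zeros(S.shape[0])))
        L = np.linalg.cholesky(S)
        z = np.linalg.solve(L, (X - mu).T)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d = S.shape[0]
        return -0.5 * (d * math.log(2 * math.pi) + logdet + (z ** 2).sum(axis=0))
    if k is Kind.ROTATED_UNIFORMS:
        w = _widths(spec)
        U = X @ _rotation(spec)
        inside = np.all(np.abs(U) <= w / 2 + 1e-12, axis=1)
        out = np.full(X.shape[0], -np.inf)
        out[inside] = -np.log(w).sum()
        return out
    if k is Kind.GAUSSIAN_MIXTURE:
        means, covs, wts = _mixture_means(spec), _mixture_covs(spec), _mixture_weights(spec)
        d = means.shape[1]
        parts = np.empty((len(wts), X.shape[0]))
        for c in range(len(wts)):
            L = np.linalg.cholesky(covs[c])
            z = np.linalg.solve(L, (X - means[c]).T)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            parts[c] = (math.log(wts[c])
                        - 0.5 * (d * math.log(2 * math.pi) + logdet + (z ** 2).sum(axis=0)))
        return logsumexp(parts, axis=0)
    if k is Kind.DOUBLE_WELL_CHAIN:
        d, a, sigma, c, tau = _chain_params(spec)
        x0 = X[:, 0]
        lp = logsumexp(np.stack([
            -0.5 * ((x0 - a) / sigma) ** 2, -0.5 * ((x0 + a) / sigma) ** 2]),
            axis=0) + math.log(0.5) - 0.5 * math.log(2 * math.pi) - math.log(sigma)
        for j in range(1, d):
            r = X[:, j] - c * X[:, j - 1]
            lp += -0.5 * (r / tau) ** 2 - 0.5 * math.log(2 * math.pi) - math.log(tau)
        return lp
    raise ParameterError(f"unknown kind {k}")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def gaussian_entropy(cov: np.ndarray) -> float:
    """½ ln((2πe)^d det Σ), nats."""
    cov = np.atleast_2d(np.asarray(cov, dtype=np.float64))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ParameterError("covariance must be positive definite")
    return 0.5 * (cov.shape[0] * _LN_2PIE + logdet)


def _dwell_marginal_entropy(a: float, sigma: float, tol: float = 1e-10) -> float:
    """1-D entropy of ½N(−a,σ²)+½N(a,σ²) by adaptive quadrature."""
    def neg_plogp(x):
        t = logsumexp([-0.5 * ((x - a) / sigma) ** 2,
                       -0.5 * ((x + a) / sigma) ** 2])
        lp = t + math.log(0.5) - 0.5 * math.log(2 * math.pi) - math.log(sigma)
        return -math.exp(lp) * lp
    lim = a + 12 * sigma
    val, err = quad(neg_plogp, -lim, lim, limit=400, epsabs=tol, epsrel=tol)
    return val


def _mixture_quadrature(spec: SyntheticSpec) -> float:
    means, covs, wts = _mixture_means(spec), _mixture_covs(spec), _mixture_weights(spec)
    d = means.shape[1]
    if d > 3:
        raise OracleError("quadrature oracle for mixtures limited to d <= 3")
    sd = math.sqrt(max(np.trace(C) for C in covs))
    lo = means.min() - 10 * sd
    hi = means.max() + 10 * sd

    def neg_plogp(*x):
        lp = float(log_density(spec, np.array(x)[None, :])[0])
        return 0.0 if lp == -np.inf else -math.exp(lp) * lp

    opts = {"limit": 200, "epsabs": 1e-6, "epsrel": 1e-6}
    val, err = nquad(neg_plogp, [[lo, hi]] * d, opts=opts)
    return val


def oracle_entropy(spec: SyntheticSpec,
                   method: OracleMethod | str | None = None,
                   n_mc: int = 200_000) -> OracleEntropy:
    """Independent reference entropy for the spec (nats)."""
    k = spec.kind
    if method is not None:
        method = OracleMethod(method)
    if method is None:
        if k in (Kind.GAUSSIAN, Kind.BLOCK_GAUSSIAN, Kind.ROTATED_UNIFORMS):
            method = OracleMethod.CLOSED_FORM
        elif k is Kind.DOUBLE_WELL_CHAIN:
            method = OracleMethod.QUADRATURE
        elif k is Kind.GAUSSIAN_MIXTURE:
            d = _mixture_means(spec).shape[1]
            method = OracleMethod.QUADRATURE if d <= 3 else OracleMethod.MONTE_CARLO

    if method is OracleMethod.CLOSED_FORM:
        if k in (Kind.GAUSSIAN, Kind.BLOCK_GAUSSIAN):
            return OracleEntropy(gaussian_entropy(exact_covariance(spec)),
                                 OracleMethod.CLOSED_FORM)
        if k is Kind.ROTATED_UNIFORMS:
            return OracleEntropy(float(np.log(_widths(spec)).sum()),
                                 OracleMethod.CLOSED_FORM)
        raise OracleError(f"no closed form for kind {k}")

    if method is OracleMethod.QUADRATURE:
        if k is Kind.DOUBLE_WELL_CHAIN:
            # chain rule: H = H(x_1) + Σ_j H(x_j | x_{j-1}); the conditionals
            # are exactly Gaussian with variance tau², so only the bimodal
            # first marginal needs numerical integration.
            d, a, sigma, c, tau = _chain_params(spec)
            h = _dwell_marginal_entropy(a, sigma)
            h += (d - 1) * 0.5 * (_LN_2PIE + 2.0 * math.log(tau))
            return OracleEntropy(h, OracleMethod.QUADRATURE)
        if k is Kind.GAUSSIAN_MIXTURE:
            return OracleEntropy(_mixture_quadrature(spec), OracleMethod.QUADRATURE)
        raise OracleError(f"no quadrature oracle for kind {k}")

    if method is OracleMethod.MONTE_CARLO:
        fresh = SyntheticSpec(kind=spec.kind, n=n_mc,
                              seed=spec.seed + 777_001, params=spec.params)
        lp = log_density(spec, sample(fresh).X)
        return OracleEntropy(float(-lp.mean()), OracleMethod.MONTE_CARLO,
                             float(lp.std(ddof=1) / math.sqrt(n_mc)))

    raise OracleError(f"unknown oracle method {method}")


def qh_gap(spec: SyntheticSpec) -> float:
    """Gaussian-fit overestimate: ½ln((2πe)^d det Σ_spec) − true entropy.

    Non-negative (up to oracle error) because the Gaussian maximises
    entropy at fixed covariance; zero exactly for pure gaussians.
    """
    return gaussian_entropy(exact_covariance(spec)) - oracle_entropy(spec).value
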