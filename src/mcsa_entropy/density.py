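"""Nonparametric differential entropy estimators.

Two estimators of the configurational entropy integral -∫p ln p:

* :func:`knn_entropy` — the Kozachenko–Leonenko k-nearest-neighbour
  estimator with digamma bias correction,

      Ĥ = ψ(n) − ψ(k) + ln V_d + (d/n) Σ_i ln R_i(k),

  where R_i(k) is the Euclidean distance from sample i to its k-th
  neighbour and V_d the volume of the d-dimensional unit ball.

* :func:`adaptive_kernel_entropy` — an adaptive anisotropic ellipsoidal
  generalisation: each point carries a unit-determinant shape matrix
  Λ_i built from a shrinkage-regularised local covariance, and R_i is
  replaced by the Λ_i-metric (Mahalanobis) distance ρ_i to the k-th
  neighbour.  Because det Λ_i = 1 the Jacobian term vanishes and the
  same digamma-corrected formula applies.  With Λ_i = I the estimator
  reduces *exactly* to :func:`knn_entropy`.

Shape matrices: the sample covariance of the ``local_k`` nearest
neighbours is noisy when local_k is not ≫ d²; it is therefore (a)
shrunk toward its isotropic part with a Ledoit–Wolf intensity and (b)
blended toward the (reliable) global covariance with weight
γ = min(1, d²/local_k).  In high dimension γ → 1 and the estimator
becomes k-NN on globally whitened data, which is the best this
estimator family can do there; in low dimension the shape is genuinely
local.

Standard errors use the batch-means method over ``stderr_blocks``
contiguous blocks of frames (contiguity respects trajectory
autocorrelation); independent estimates on the blocks have ≈ the same
variance as the pooled estimate has at full n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .exceptions import EstimationError, ParameterError
from .units import GAS_CONSTANT_R, J_PER_MOL_K, NATS

log = logging.getLogger(__name__)

# below this sample count, neighbour searches run as exact all-pairs
# float64 sweeps (reference path used by the brute-force equivalence test)
_SMALL_N = 2048
# cKDTree wins over blocked matrix products only in low dimension
_TREE_MAX_D = 10


class Kernel(str, Enum):
    KNN_ISOTROPIC = "knn_isotropic"
    ADAPTIVE_ELLIPSOID = "adaptive_ellipsoid"


class MarginalMethod(str, Enum):
    KNN_1D = "knn_1d"
    HISTOGRAM = "histogram"


@dataclass
class EstimatorConfig:
    """Tunable constants of the density estimators.

    k               neighbour rank entering the digamma formula (small k
                    keeps bias minimal).
    kernel          isotropic k-NN or the adaptive ellipsoidal kernel.
    local_k         neighbourhood size for the local shape estimate;
                    ``None`` → min(n−1, max(4(d+1), min(2000, n//10))).
    shape_regularizer  ε added to the local covariance diagonal;
                    ``None`` → 1e-10 · trace/d.
    global_blend    weight γ of the global covariance in the shape
                    blend; ``None`` → min(1, d²/local_k).
    identity_shape  force Λ_i = I (isotropic limiting case; reproduces
                    knn_entropy bit for bit).
    search_pool     Euclidean candidate pool searched for the k-th
                    Mahalanobis neighbour; ``None`` → max(512, local_k).
    marginal_method estimator used by marginal_entropy_1d.
    jitter_duplicates  resolve exactly duplicated rows by a seeded
                    deterministic jitter of 1e-8 × column stdev instead
                    of failing.
    stderr_blocks   batch-means blocks for standard errors (0 disables).
    """

    k: int = 5
    kernel: Kernel = Kernel.ADAPTIVE_ELLIPSOID
    local_k: int | None = None
    shape_regularizer: float | None = None
    global_blend: float | None = None
    identity_shape: bool = False
    search_pool: int | None = None
    marginal_method: MarginalMethod = MarginalMethod.KNN_1D
    jitter_duplicates: bool = False
    jitter_seed: int = 0
    stderr_blocks: int = 5

    def __post_init__(self):
        self.kernel = Kernel(self.kernel)
        self.marginal_method = MarginalMethod(self.marginal_method)
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")


@dataclass
class EntropyEstimate:
    """A differential entropy with provenance."""

    value: float
    units: str = NATS
    estimator: str = "knn"
    d: int = 1
    n: int = 2
    stderr: float | None = None

    def in_units(self, units: str) -> "EntropyEstimate":
        if units == self.units:
            return self
        if {units, self.units} != {NATS, J_PER_MOL_K}:
            raise ParameterError(f"unknown units {units!r}")
        f = GAS_CONSTANT_R if units == J_PER_MOL_K else 1.0 / GAS_CONSTANT_R
        return replace(self, value=self.value * f, units=units,
                       stderr=None if self.stderr is None else self.stderr * f)


def unit_ball_volume(d: int) -> float:
    """Volume of the d-dimensional Euclidean unit ball, π^(d/2)/Γ(d/2+1)."""
    if d < 1:
        raise ParameterError(f"dimension must be >= 1, got {d}")
    return math.exp(ln_unit_ball_volume(d))


def ln_unit_ball_volume(d: int) -> float:
    if d < 1:
        raise ParameterError(f"dimension must be >= 1, got {d}")
    return (d / 2.0) * math.log(math.pi) - gammaln(d / 2.0 + 1.0)


# ---------------------------------------------------------------------------
# neighbour backends
# ---------------------------------------------------------------------------

def _as_matrix(X) -> np.ndarray:
    A = np.asarray(getattr(X, "X", X), dtype=np.float64)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2:
        raise ParameterError("expected an (n, d) sample matrix")
    if not np.all(np.isfinite(A)):
        raise ParameterError("sample matrix contains non-finite values")
    return A


def _check_duplicates(r2_k1: np.ndarray, context: str) -> None:
    zero = np.flatnonzero(r2_k1 <= 0.0)
    if zero.size:
        raise EstimationError(
            f"{context}: {zero.size} sample row(s) (first index {zero[0]}) have "
            "an exactly coincident neighbour, so the nearest-neighbour radius is "
            "zero. Deduplicate the frames or set jitter_duplicates=True "
            "(deterministic seeded jitter of 1e-8 x column stdev)."
        )


def _apply_jitter(A: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    scale = 1e-8 * A.std(axis=0)
    scale[scale == 0.0] = 1e-8
    return A + rng.standard_normal(A.shape) * scale


def nearest_neighbors(A: np.ndarray, m: int, return_indices: bool = False):
    """Sorted squared Euclidean distances (and indices) of the m nearest
    neighbours of every row, self excluded.

    Exact for every path: all-pairs float64 for small n, a k-d tree in low
    dimension, blocked float32 matrix products otherwise (the float32 path
    trades ~1e-7 relative distance error for an order-of-magnitude speedup;
    negligible against estimator noise at the sample sizes where it runs).
    """
    n, d = A.shape
    if not 1 <= m < n:
        raise ParameterError(f"need 1 <= m < n, got m={m}, n={n}")
    if n <= _SMALL_N:
        return _nearest_small(A, m, return_indices)
    if d <= _TREE_MAX_D:
        tree = cKDTree(A)
        dist, idx = tree.query(A, k=m + 1, workers=1)
        d2 = dist[:, 1:] ** 2
        return (d2, idx[:, 1:]) if return_indices else d2
    return _nearest_blocked(A, m, return_indices)


def _nearest_small(A: np.ndarray, m: int, return_indices: bool):
    n, d = A.shape
    d2 = np.empty((n, m))
    idx = np.empty((n, m), dtype=np.int64) if return_indices else None
    chunk = max(1, int(2e7 / (n * d)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        diff = A[s:e, None, :] - A[None, :, :]
        D = np.einsum("cij,cij->ci", diff, diff)
        D[np.arange(e - s), np.arange(s, e)] = np.inf
        part = np.argpartition(D, m - 1, axis=1)[:, :m]
        dd = np.take_along_axis(D, part, 1)
        order = np.argsort(dd, axis=1, kind="stable")
        d2[s:e] = np.take_along_axis(dd, order, 1)
        if return_indices:
            idx[s:e] = np.take_along_axis(part, order, 1)
    return (d2, idx) if return_indices else d2


def _nearest_blocked(A: np.ndarray, m: int, return_indices: bool):
    n, d = A.shape
    F = np.ascontiguousarray(A, dtype=np.float32)
    sq = np.einsum("ij,ij->i", F, F)
    d2 = np.empty((n, m))
    idx = np.empty((n, m), dtype=np.int64) if return_indices else None
    chunk = max(64, int(4e8 / (8 * n)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        D = sq[s:e, None] + sq[None, :] - 2.0 * (F[s:e] @ F.T)
        np.maximum(D, 0.0, out=D)
        D[np.arange(e - s), np.arange(s, e)] = np.inf
        part = np.argpartition(D, m - 1, axis=1)[:, :m]
        dd = np.take_along_axis(D, part, 1)
        order = np.argsort(dd, axis=1, kind="stable")
        sub = np.take_along_axis(part, order, 1)
        # refine the kept distances in float64 to wash out GEMM cancellation
        diff = A[s:e, None, :] - A[sub]
        d2[s:e] = np.einsum("cmj,cmj->cm", diff, diff)
        if return_indices:
            idx[s:e] = sub
    return (d2, idx) if return_indices else d2


# ---------------------------------------------------------------------------
# k-NN estimator
# ---------------------------------------------------------------------------

def _kl_from_log_radii(n: int, d: int, k: int, ln_r: np.ndarray) -> float:
    return float(digamma(n) - digamma(k) + ln_unit_ball_volume(d)
                 + (d / n) * ln_r.sum())


def _batch_means_stderr(A: np.ndarray, blocks: int, estimate_fn) -> float | None:
    n = A.shape[0]
    if blocks < 2 or n < 4 * blocks:
        return None
    edges = np.linspace(0, n, blocks + 1, dtype=int)
    vals = [estimate_fn(A[s:e]) for s, e in zip(edges[:-1], edges[1:])]
    return float(np.std(vals, ddof=1) / math.sqrt(blocks))


def knn_entropy(X, k: int = 5, *, jitter_duplicates: bool = False,
                jitter_seed: int = 0, stderr_blocks: int = 5) -> EntropyEstimate:
    """Kozachenko–Leonenko differential entropy estimate in nats."""
    A = _as_matrix(X)
    n, d = A.shape
    if not 1 <= k < n:
        raise ParameterError(f"need 1 <= k < n, got k={k}, n={n}")

    def core(B: np.ndarray) -> float:
        d2 = nearest_neighbors(B, k)[:, k - 1]
        _check_duplicates(d2, "knn_entropy")
        return _kl_from_log_radii(B.shape[0], d, k, 0.5 * np.log(d2))

    if jitter_duplicates:
        A = _apply_jitter(A, jitter_seed)
    value = core(A)
    stderr = _batch_means_stderr(A, stderr_blocks, core)
    return EntropyEstimate(value=value, estimator=f"knn(k={k})", d=d, n=n,
                           stderr=stderr)


# ---------------------------------------------------------------------------
# adaptive anisotropic ellipsoidal kernel
# ---------------------------------------------------------------------------

def _resolve_local_k(cfg: EstimatorConfig, n: int, d: int) -> int:
    lk = cfg.local_k
    if lk is None:
        # large neighbourhoods in low d (where locality is resolvable),
        # shrinking as 1/d² so that the global blend takes over smoothly
        lk = min(n - 1, max(4 * (d + 1), 8192 // (d * d)))
    if lk < d + 1:
        raise ParameterError(
            f"local_k must be >= d+1 for the adaptive kernel (local_k={lk}, d={d})")
    if lk >= n:
        raise ParameterError(f"local_k={lk} must be < n={n}")
    return lk


def _ledoit_wolf_shrink(C: np.ndarray, Z: np.ndarray, m: int, d: int) -> np.ndarray:
    """Batched Ledoit–Wolf shrinkage of (c,d,d) covariances toward μI."""
    mu = np.trace(C, axis1=1, axis2=2) / d
    nrm4 = (np.einsum("cpi,cpi->cp", Z, Z) ** 2).sum(axis=1)
    c2 = np.einsum("cij,cij->c", C, C)
    b2 = np.maximum(nrm4 / m**2 - c2 / m, 0.0)
    delta2 = np.maximum(c2 - d * mu**2, 1e-300)
    gamma = np.clip(b2 / delta2, 0.0, 1.0)
    out = (1.0 - gamma)[:, None, None] * C
    out[:, np.arange(d), np.arange(d)] += (gamma * mu)[:, None]
    return out


def _unit_det_shape(C: np.ndarray, eps: float) -> np.ndarray:
    """Cholesky factors of C + εI scaled so det(shape) = 1 is accounted
    for; returns (L, logdet) so callers can rescale distances."""
    d = C.shape[-1]
    C = C.copy()
    C[..., np.arange(d), np.arange(d)] += eps
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise EstimationError(
            "singular local covariance; raise shape_regularizer") from err
    logdet = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
    return L, logdet


def adaptive_kernel_entropy(X, cfg: EstimatorConfig | None = None) -> EntropyEstimate:
    """Adaptive anisotropic ellipsoidal-kernel entropy estimate in nats.

    See the module docstring for the construction.  ``cfg.identity_shape``
    forces Λ_i = I, in which case the result equals :func:`knn_entropy`
    on the same data bit for bit.
    """
    cfg = cfg or EstimatorConfig()
    if cfg.kernel is not Kernel.ADAPTIVE_ELLIPSOID:
        raise ParameterError("cfg.kernel must be adaptive_ellipsoid")
    A = _as_matrix(X)
    if cfg.jitter_duplicates:
        A = _apply_jitter(A, cfg.jitter_seed)
    n, d = A.shape
    k = cfg.k
    if not 1 <= k < n:
        raise ParameterError(f"need 1 <= k < n, got k={k}, n={n}")

    tag = f"adaptive_ellipsoid(k={k})"

    if cfg.identity_shape:
        def core_iso(B: np.ndarray) -> float:
            d2 = nearest_neighbors(B, k)[:, k - 1]
            _check_duplicates(d2, "adaptive_kernel_entropy")
            return _kl_from_log_radii(B.shape[0], d, k, 0.5 * np.log(d2))
        value = core_iso(A)
        stderr = _batch_means_stderr(A, cfg.stderr_blocks, core_iso)
        return EntropyEstimate(value=value, estimator=tag + "[identity]",
                               d=d, n=n, stderr=stderr)

    local_k = _resolve_local_k(cfg, n, d)
    gamma = cfg.global_blend
    if gamma is None:
        gamma = 1.0 if d == 1 else min(1.0, d * d / local_k)

    def core(B: np.ndarray) -> float:
        return _adaptive_core(B, k, local_k, gamma, cfg)

    value = core(A)
    stderr = _batch_means_stderr(A, cfg.stderr_blocks, core)
    return EntropyEstimate(value=value, estimator=tag, d=d, n=n, stderr=stderr)


def _adaptive_core(A: np.ndarray, k: int, local_k: int, gamma: float,
                   cfg: EstimatorConfig) -> float:
    n, d = A.shape
    local_k = min(local_k, n - 1)
    Cg = np.cov(A, rowvar=False).reshape(d, d)
    trg = max(np.trace(Cg), 1e-300)

    if gamma >= 1.0:
        # pure global shape: whiten once, then exact Euclidean k-NN
        eps = cfg.shape_regularizer
        eps = (1e-10 * trg / d) if eps is None else eps
        L, logdet = _unit_det_shape(Cg[None], eps)
        W = np.linalg.solve(L[0], A.T).T * math.exp(logdet[0] / (2 * d))
        d2 = nearest_neighbors(W, k)[:, k - 1]
        _check_duplicates(d2, "adaptive_kernel_entropy")
        return _kl_from_log_radii(n, d, k, 0.5 * np.log(d2))

    pool = min(cfg.search_pool or max(256, 16 * k), n - 1)
    _, idx = nearest_neighbors(A, pool, return_indices=True)

    # the shape field varies on the local_k scale, so it is evaluated on a
    # landmark subgrid of that resolution and looked up by nearest landmark
    stride = max(1, local_k // 256)
    land = np.arange(0, n, stride)
    L_land, logdet_land = _landmark_shapes(A, land, local_k, gamma, Cg, trg, cfg)
    if stride == 1:
        lab = np.arange(n)
    else:
        lab = cKDTree(A[land]).query(A, k=1, workers=1)[1]

    lnrho = np.empty(n)
    chunk = max(16, int(2e8 / (8 * pool * d)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        diffs = A[idx[s:e]] - A[s:e, None, :]       # (c, pool, d)
        Lc = L_land[lab[s:e]]
        y = np.linalg.solve(Lc, diffs.transpose(0, 2, 1))
        m2 = np.einsum("cdp,cdp->cp", y, y) \
            * np.exp(logdet_land[lab[s:e]] / d)[:, None]
        rho2 = np.partition(m2, k - 1, axis=1)[:, k - 1]
        _check_duplicates(rho2, "adaptive_kernel_entropy")
        lnrho[s:e] = 0.5 * np.log(rho2)
    return _kl_from_log_radii(n, d, k, lnrho)


def _landmark_shapes(A: np.ndarray, land: np.ndarray, local_k: int,
                     gamma: float, Cg: np.ndarray, trg: float,
                     cfg: EstimatorConfig):
    """Unit-determinant shape Cholesky factors at the landmark points."""
    n, d = A.shape
    Gs = Cg / trg
    _, idx = _landmark_neighbors(A, land, local_k)
    Ls = np.empty((land.size, d, d))
    logdets = np.empty(land.size)
    chunk = max(8, int(2e8 / (8 * local_k * d)))
    for s in range(0, land.size, chunk):
        e = min(s + chunk, land.size)
        loc = A[idx[s:e]]
        Z = loc - loc.mean(axis=1, keepdims=True)
        C = np.einsum("cpi,cpj->cij", Z, Z) / local_k
        C = _ledoit_wolf_shrink(C, Z, local_k, d)
        tr = np.maximum(np.trace(C, axis1=1, axis2=2), 1e-300)
        S = (1.0 - gamma) * C / tr[:, None, None] + gamma * Gs
        eps = cfg.shape_regularizer
        eps = 1e-10 / d if eps is None else eps
        L, logdet = _unit_det_shape(S, eps)
        Ls[s:e] = L
        logdets[s:e] = logdet
    return Ls, logdets


def _landmark_neighbors(A: np.ndarray, land: np.ndarray, m: int):
    n, d = A.shape
    if n <= _SMALL_N or d > _TREE_MAX_D:
        d2, idx = nearest_neighbors(A, m, return_indices=True)
        return d2[land], idx[land]
    tree = cKDTree(A)
    dist, idx = tree.query(A[land], k=m + 1, workers=1)
    return dist[:, 1:] ** 2, idx[:, 1:]


# ---------------------------------------------------------------------------
# 1-D marginals
# ---------------------------------------------------------------------------

def _knn_1d_log_radii(x: np.ndarray, k: int) -> np.ndarray:
    """k-th neighbour distances in 1-D via a sorted sliding window."""
    n = x.size
    order = np.argsort(x, kind="stable")
    a = x[order]
    left = np.concatenate([np.full(k, -np.inf), a])
    right = np.concatenate([a, np.full(k, np.inf)])
    # distances to the k nearest on each side, then k-th smallest of the 2k
    cand = np.empty((n, 2 * k))
    for j in range(1, k + 1):
        cand[:, j - 1] = a - left[k - j:k - j + n]
        cand[:, k + j - 1] = right[j:j + n] - a
    rk = np.partition(cand, k - 1, axis=1)[:, k - 1]
    out = np.empty(n)
    out[order] = rk
    return out


def marginal_entropy_1d(x, method: MarginalMethod | str = MarginalMethod.KNN_1D,
                        k: int = 5, stderr_blocks: int = 0) -> EntropyEstimate:
    """Fast 1-D marginal differential entropy (nats)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    if n < 10:
        raise ParameterError(f"need n >= 10 samples, got {n}")
    if np.ptp(x) == 0.0:
        raise EstimationError("constant column has entropy -infinity")
    method = MarginalMethod(method)

    if method is MarginalMethod.KNN_1D:
        def core(b: np.ndarray) -> float:
            r = _knn_1d_log_radii(b, k)
            _check_duplicates(r, "marginal_entropy_1d")
            return _kl_from_log_radii(b.size, 1, k, np.log(r))
        tag = f"marginal_knn1d(k={k})"
    else:
        def core(b: np.ndarray) -> float:
            return histogram_entropy(b)
        tag = "marginal_histogram"

    value = core(x)
    stderr = None
    if stderr_blocks >= 2:
        stderr = _batch_means_stderr(x[:, None], stderr_blocks,
                                     lambda B: core(B.ravel()))
    return EntropyEstimate(value=value, estimator=tag, d=1, n=n, stderr=stderr)


def histogram_bin_count(n: int) -> int:
    """Rice rule, floored at 16 bins."""
    return max(16, int(round(2.0 * n ** (1.0 / 3.0))))


def histogram_entropy(x: np.ndarray) -> float:
    """Plug-in histogram entropy with the analytic ln(bin width) correction."""
    x = np.asarray(x, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise EstimationError("constant column has entropy -infinity")
    nb = histogram_bin_count(x.size)
    counts, _ = np.histogram(x, bins=nb, range=(lo, hi))
    p = counts[counts > 0] / x.size
    width = (hi - lo) / nb
    return float(-(p * np.log(p)).sum() + math.log(width))
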