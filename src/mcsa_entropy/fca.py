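"""Full Correlation Analysis.

Finds an orthonormal change of basis W that minimises the summed 1-D
marginal entropies of the transformed modes Y = X Wᵀ.  Because an
orthonormal transform leaves the joint entropy invariant, minimising
Σ_i H(y_i) minimises the total mutual information
I = Σ_i H(y_i) − H(y) and therefore decouples the modes as far as a
linear transform can — a non-Gaussian generalisation of PCA.

Optimisation: PCA initialisation, then Jacobi sweeps over all mode
pairs.  For each pair a planar rotation angle is chosen by a 3° grid
scan over [0°, 90°) (sufficient by the 90° symmetry of a pair
rotation) followed by golden-section refinement; a rotation is applied
only if it lowers the pair's summed marginal entropy, which makes the
per-sweep objective trace non-increasing by construction.  Inner-loop
marginals use the fast histogram estimator; reported mutual
informations use k-NN estimates (see :func:`mutual_information_pair`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .density import histogram_entropy, knn_entropy
from .ensemble_io import SampleMatrix
from .exceptions import EstimationError, ParameterError

log = logging.getLogger(__name__)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class OrthonormalTransform:
    """d × d orthonormal transform with its optimisation history."""

    W: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    sweeps: int = 0
    tol: float = 0.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        d = self.W.shape[0]
        if self.W.shape != (d, d):
            raise ParameterError("W must be square")
        drift = np.abs(self.W @ self.W.T - np.eye(d)).max()
        if drift > 1e-8:
            raise ParameterError(f"W is not orthonormal (drift {drift:.2e})")


def _pca_axes(X: np.ndarray) -> np.ndarray:
    C = np.cov(X, rowvar=False)
    evals, vecs = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(evals)[::-1]
    W = vecs[:, order].T
    # deterministic sign: largest-magnitude component of each axis positive
    for r in range(W.shape[0]):
        j = np.argmax(np.abs(W[r]))
        if W[r, j] < 0:
            W[r] = -W[r]
    return W


def _golden_min(f, lo: float, hi: float, iters: int = 28):
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc <= fd:          # ties toward smaller angle
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc <= fd else (d, fd)


def fca_transform(X, tol: float | None = None, max_sweeps: int = 50,
                  seed: int = 0, init: str = "pca",
                  grid_deg: float = 3.0) -> tuple[OrthonormalTransform, SampleMatrix]:
    """Minimise Σ_i Ĥ(marginal i) over orthonormal transforms.

    Returns the transform and Y = X Wᵀ.  ``tol`` is the minimum
    objective improvement (nats) a full sweep must achieve to continue;
    default 0.001 × d.  ``seed`` is accepted for interface symmetry with
    the MI estimators — the sweep itself is deterministic (lexicographic
    pair order, deterministic grid).
    """
    A = np.asarray(getattr(X, "X", X), dtype=np.float64)
    n, d = A.shape
    if d < 2:
        raise ParameterError("FCA needs d >= 2 modes")
    if n < 100:
        log.warning("FCA on only n=%d samples; marginal entropies will be noisy", n)
    if tol is None:
        tol = 0.001 * d

    if init == "pca":
        W = _pca_axes(A)
    elif init == "identity":
        W = np.eye(d)
    else:
        raise ParameterError(f"unknown init {init!r}")
    Y = A @ W.T

    def marg(col: np.ndarray, pair=None) -> float:
        h = histogram_entropy(col)
        if not np.isfinite(h):
            raise EstimationError(
                f"non-finite marginal entropy during FCA sweep at pair {pair}")
        return h

    H = np.array([marg(Y[:, i]) for i in range(d)])
    trace = [float(H.sum())]
    reorth = 0
    sweeps_done = 0

    for sweep in range(max_sweeps):
        before = H.sum()
        for i in range(d - 1):
            for j in range(i + 1, d):
                yi, yj = Y[:, i].copy(), Y[:, j].copy()

                def pair_obj(theta: float) -> float:
                    if theta == 0.0:
                        return H[i] + H[j]
                    c, s = math.cos(theta), math.sin(theta)
                    return (marg(c * yi - s * yj, (i, j))
                            + marg(s * yi + c * yj, (i, j)))

                angles = np.deg2rad(np.arange(0.0, 90.0, grid_deg))
                vals = [pair_obj(t) for t in angles]
                b = int(np.argmin(vals))
                span = math.radians(grid_deg)
                t_best, f_best = _golden_min(
                    pair_obj, max(0.0, angles[b] - span), angles[b] + span)
                if vals[b] < f_best:
                    t_best, f_best = angles[b], vals[b]
                if t_best != 0.0 and f_best < H[i] + H[j]:
                    c, s = math.cos(t_best), math.sin(t_best)
                    Y[:, i] = c * yi - s * yj
                    Y[:, j] = s * yi + c * yj
                    wi, wj = W[i].copy(), W[j].copy()
                    W[i] = c * wi - s * wj
                    W[j] = s * wi + c * wj
                    H[i] = marg(Y[:, i], (i, j))
                    H[j] = marg(Y[:, j], (i, j))
        drift = np.abs(W @ W.T - np.eye(d)).max()
        if drift > 1e-8:
            Q, R = np.linalg.qr(W.T)
            W = (Q * np.sign(np.diag(R))).T
            Y = A @ W.T
            H = np.array([marg(Y[:, k]) for k in range(d)])
            reorth += 1
        sweeps_done = sweep + 1
        trace.append(float(H.sum()))
        if before - H.sum() < tol:
            break

    if reorth:
        log.info("re-orthonormalised W %d time(s) during FCA", reorth)
    t = OrthonormalTransform(W=W, objective_trace=trace, sweeps=sweeps_done,
                             tol=tol)
    return t, SampleMatrix(X=Y, weighting=getattr(X, "weighting", "plain"))


def mutual_information_pair(x, y, seed: int = 0, k: int = 5,
                            clamp: bool = True) -> float:
    """Pairwise mutual information (nats) with a fill-mode reference.

    I(x, y) = Ĥ₂(x, π(y)) − Ĥ₂(x, y) where π is a seeded random row
    permutation of y.  Both joint entropies are estimated with the same
    2-D k-NN estimator at the same sample size, so the
    dimension-dependent estimator bias cancels.  Small negative results
    (estimator noise at independence) are clamped to 0 with the raw
    value logged; pass ``clamp=False`` to keep the raw value.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 100:
        raise ParameterError("mutual information needs n >= 100 samples")
    perm = np.random.default_rng(seed).permutation(y.size)
    h_dec = knn_entropy(np.column_stack([x, y[perm]]), k=k, stderr_blocks=0).value
    h_joint = knn_entropy(np.column_stack([x, y]), k=k, stderr_blocks=0).value
    raw = h_dec - h_joint
    if raw < 0 and clamp:
        log.debug("clamping negative pairwise MI %.4g to 0", raw)
        return 0.0
    return raw
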