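"""Mode clustering into minimally coupled subspaces.

Pairwise mutual informations between FCA modes are mapped to the
generalized correlation coefficient

    r_ij = sqrt(1 − exp(−2 I_ij)) ∈ [0, 1],

which equals |ρ| for bivariate gaussians and captures non-linear
dependence otherwise.  Modes are clustered by single-linkage threshold
graph components (every pair with r > r_c shares a cluster), and
clusters larger than ``s_max`` are subdivided by constrained
average-linkage agglomeration so that no density estimate inside the
mutual-information expansion ever exceeds the validated estimator
dimension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import EstimationError, ParameterError
from .fca import mutual_information_pair

log = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-12

# clustering-threshold presets: default, and the hi/lo pair used by the
# threshold-insensitivity check
R_C_DEFAULT = 0.25
R_C_PRESETS = {"default": 0.25, "hi": 0.4, "lo": 0.15}


def generalized_correlation(mi: np.ndarray) -> np.ndarray:
    """r = sqrt(1 − exp(−2 I)), clamped to [0, 1 − 1e-12]."""
    mi = np.maximum(np.asarray(mi, dtype=np.float64), 0.0)
    return np.clip(np.sqrt(-np.expm1(-2.0 * mi)), 0.0, R_CLIP)


@dataclass
class CorrelationMatrix:
    R: np.ndarray
    mi: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        self.mi = np.asarray(self.mi, dtype=np.float64)
        d = self.R.shape[0]
        if self.R.shape != (d, d) or self.mi.shape != (d, d):
            raise ParameterError("R and mi must be square matrices of equal size")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ParameterError("R diagonal must be 1")
        off = self.R[~np.eye(d, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ParameterError("off-diagonal R entries must lie in [0, 1]")

    @property
    def d(self) -> int:
        return self.R.shape[0]


@dataclass
class ModePartition:
    """Disjoint clusters of mode indices covering 0..d−1, plus the
    subdivision of oversized clusters into subclusters of size ≤ s_max."""

    clusters: list[list[int]]
    d: int
    threshold: float
    s_max: int | None = None
    subclusters: dict[int, list[list[int]]] = field(default_factory=dict)

    def __post_init__(self):
        seen = sorted(i for c in self.clusters for i in c)
        if seen != list(range(self.d)):
            raise ParameterError("clusters must disjointly cover all modes")
        for ci, subs in self.subclusters.items():
            parent = set(self.clusters[ci])
            sub_all = sorted(i for s in subs for i in s)
            if sub_all != sorted(parent):
                raise ParameterError(
                    f"subclusters of cluster {ci} must disjointly cover it")
            if self.s_max is not None and any(len(s) > self.s_max for s in subs):
                raise ParameterError(f"subcluster exceeds s_max={self.s_max}")

    def cluster_sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def correlation_matrix(Y, seed: int = 0, k: int = 5,
                       max_samples: int | None = 20_000) -> CorrelationMatrix:
    """Pairwise MI and generalized correlation over all mode pairs.

    ``max_samples`` caps the rows used per pair estimate (contiguous
    prefix, deterministic) — pairwise MI for clustering does not need
    the full trajectory and the cap keeps the d² pair sweep affordable.
    """
    A = np.asarray(getattr(Y, "X", Y), dtype=np.float64)
    n, d = A.shape
    if d < 2:
        raise ParameterError("correlation matrix needs d >= 2 modes")
    if max_samples is not None and n > max_samples:
        A = A[:max_samples]
    mi = np.zeros((d, d))
    for i, j in combinations(range(d), 2):
        try:
            v = mutual_information_pair(A[:, i], A[:, j],
                                        seed=seed + 7919 * i + j, k=k)
        except Exception as err:
            raise EstimationError(
                f"MI estimation failed for mode pair ({i}, {j}): {err}") from err
        mi[i, j] = mi[j, i] = v
    R = generalized_correlation(mi)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(mi, 0.0)
    return CorrelationMatrix(R=R, mi=mi)


def threshold_cluster(R: CorrelationMatrix, r_c: float = R_C_DEFAULT) -> ModePartition:
    """Connected components of the graph with edges {(i,j): R_ij > r_c},
    sorted by smallest member index (single-linkage semantics)."""
    if not 0.0 < r_c < 1.0:
        raise ParameterError(f"threshold must satisfy 0 < r_c < 1, got {r_c}")
    d = R.d
    adj = (R.R > r_c).astype(np.int8)
    np.fill_diagonal(adj, 0)
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, []).append(i)
    clusters = sorted(comps.values(), key=lambda c: c[0])
    return ModePartition(clusters=[sorted(c) for c in clusters], d=d,
                         threshold=r_c)


def subdivide_oversized(p: ModePartition, R: CorrelationMatrix,
                        s_max: int) -> ModePartition:
    """Split clusters larger than s_max by constrained average-linkage
    agglomeration: starting from singletons, repeatedly merge the pair
    of subclusters with the highest mean inter-set R whose combined size
    stays ≤ s_max (ties toward the lowest indices); stop when no merge
    is feasible."""
    if s_max < 1:
        raise ParameterError(f"s_max must be >= 1, got {s_max}")
    subclusters: dict[int, list[list[int]]] = {}
    for ci, cluster in enumerate(p.clusters):
        if len(cluster) <= s_max:
            continue
        subclusters[ci] = _agglomerate(cluster, R.R, s_max)
    return ModePartition(clusters=p.clusters, d=p.d, threshold=p.threshold,
                         s_max=s_max, subclusters=subclusters)


def _agglomerate(members: list[int], R: np.ndarray, s_max: int) -> list[list[int]]:
    sets: list[list[int]] = [[m] for m in sorted(members)]
    while True:
        best = None
        for a in range(len(sets) - 1):
            for b in range(a + 1, len(sets)):
                if len(sets[a]) + len(sets[b]) > s_max:
                    continue
                score = float(np.mean(R[np.ix_(sets[a], sets[b])]))
                if best is None or score > best[0] + 1e-15:
                    best = (score, a, b)
        if best is None:
            break
        _, a, b = best
        merged = sorted(sets[a] + sets[b])
        sets = [s for idx, s in enumerate(sets) if idx not in (a, b)]
        sets.append(merged)
        sets.sort(key=lambda s: s[0])
    return sets


def residual_coupling_report(p: ModePartition, R: CorrelationMatrix) -> dict:
    """Diagnostics for the neglected inter-cluster coupling: the summed
    pairwise MI over all inter-cluster pairs (a proxy lower bound on the
    residual entropy, nats) and the maximum inter-cluster r."""
    label = np.empty(p.d, dtype=int)
    for ci, c in enumerate(p.clusters):
        label[c] = ci
    total_mi = 0.0
    max_r = 0.0
    npairs = 0
    for i, j in combinations(range(p.d), 2):
        if label[i] != label[j]:
            total_mi += max(R.mi[i, j], 0.0)
            max_r = max(max_r, R.R[i, j])
            npairs += 1
    out = {"inter_cluster_mi_nats": float(total_mi),
           "max_inter_cluster_r": float(max_r),
           "inter_cluster_pairs": npairs}
    log.info("residual coupling: sum MI=%.4g nats over %d inter-cluster "
             "pairs, max r=%.3f", total_mi, npairs, max_r)
    return out
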