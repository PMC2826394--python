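"""Mutual information expansion with fill modes and consistent dimensions.

An oversized cluster, split into K subclusters, has its joint entropy
approximated by the inclusion–exclusion (mutual-information) expansion
truncated at order M ∈ {2, 3}.  Expanded over entropy rather than
correlation terms the truncation is a signed sum

    S_MIE(M) = Σ_{m=1}^{M} coeff(m) · Σ_{|T|=m} S(T)

with integer coefficients fixed by the inclusion–exclusion algebra
(:func:`derive_coefficients`); e.g. coeff = (+1 at order 2, −(K−2) at
order 1) for M = 2.

Nearest-neighbour density estimates carry a dimension-dependent bias,
so naively mixing S(T) terms of different dimension biases the signed
sum.  Two devices fix this:

* **fill modes** — a subcluster block can be appended to a term after a
  single joint row permutation (:func:`fill_block`), which preserves its
  internal joint density but destroys every correlation to the rest;
* **consistent dimensions** — every term is padded with fill blocks to
  one common ``target_dim`` (the largest order-M union), so all
  estimates share the same dimension, sample size, and hence bias.

A filled estimate equals the real term's entropy plus the fill blocks'
entropies (additivity under independence).  The coefficients applied to
the filled estimates are therefore *re-derived* by solving the linear
bookkeeping system that makes every fill contribution cancel and every
real term appear with its inclusion–exclusion coefficient; the solve
residual is asserted against the exact algebra before any result is
returned.  Fill blocks are assigned cyclically (starting after the
highest member of a term), which keeps that system consistent; a block
is truncated to a prefix when an exact dimension match requires it, and
each distinct prefix then enters the system as an auxiliary estimated
term of its own.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .density import (EntropyEstimate, EstimatorConfig, Kernel,
                      adaptive_kernel_entropy, knn_entropy)
from .exceptions import EstimationError, ParameterError

log = logging.getLogger(__name__)

TermKey = tuple  # ("T", blocks...) for real subsets, ("B", block, ncols) prefixes


@dataclass
class FillPlan:
    """Which blocks enter each term as real data and which as permuted
    fills; every term's real+fill dimension equals target_dim.

    ``scheme`` is "block" (cyclic whole-block fills, truncating the last
    block) or "replica" (every fill column is an independently permuted
    copy of one anchor mode; always yields a solvable cancellation
    system).  A fill entry (−1, j) denotes j anchor-replica columns.
    """

    target_dim: int
    assignments: dict[TermKey, list[tuple[int, int]]]
    seed: int = 0
    scheme: str = "block"

REPLICA = -1  # fill-entry block id for anchor-mode replica columns


@dataclass
class MIETerms:
    """Audit record of one expansion: every estimated term, the filled
    dimension it was computed at, and its solved coefficient."""

    order: int
    coefficients: dict[int, int]
    joint_entropies: dict[TermKey, dict] = field(default_factory=dict)
    plan: FillPlan | None = None


def fill_block(Y, block, seed: int = 0) -> np.ndarray:
    """Return the block's columns under ONE seeded joint row permutation.

    Intra-block structure is preserved exactly; correlation to every
    other column is destroyed.
    """
    A = np.asarray(getattr(Y, "X", Y), dtype=np.float64)
    block = list(block)
    if not block:
        raise ParameterError("fill block must be non-empty")
    perm = np.random.default_rng(seed).permutation(A.shape[0])
    return A[np.ix_(perm, block)]


def derive_coefficients(K: int, M: int) -> dict[int, int]:
    """Signed multipliers of Σ_{|T|=m} S(T) in the order-M expansion.

    Derived by symbolically expanding Σ_m (−1)^{m+1} Σ_{|T|=m} I_m(T)
    with I_m(T) = −Σ_{∅≠U⊆T} (−1)^{|U|} S(U), collecting entropy terms
    by subset size (all subsets of one size share a coefficient by
    symmetry).
    """
    if K < 2:
        raise ParameterError(f"need K >= 2 subclusters, got {K}")
    if M not in (2, 3):
        raise ParameterError(f"truncation order must be 2 or 3, got {M}")
    if M > K:
        raise ParameterError(f"truncation order M={M} exceeds K={K} subclusters")
    coeff = {m: 0 for m in range(1, M + 1)}
    for m in range(1, M + 1):
        sign_outer = (-1) ** (m + 1)
        # I_m over a size-m subset T contributes (-1)^(u+1) to each of its
        # C(m, u) size-u subsets; T itself ranges over C(K, m) subsets, and a
        # fixed size-u subset U lies in C(K-u, m-u) of them.
        for u in range(1, m + 1):
            coeff[u] += sign_outer * (-1) ** (u + 1) * math.comb(K - u, m - u)
    return coeff


# ---------------------------------------------------------------------------
# fill planning and bookkeeping
# ---------------------------------------------------------------------------

def _cyclic_fills(start: int, exclude: set[int], need: int,
                  sizes: list[int]) -> list[tuple[int, int]]:
    """Whole blocks (last possibly truncated) scanned cyclically from
    ``start``, skipping ``exclude``, until exactly ``need`` columns."""
    K = len(sizes)
    fills: list[tuple[int, int]] = []
    for step in range(K):
        if need == 0:
            break
        b = (start + step) % K
        if b in exclude:
            continue
        take = min(sizes[b], need)
        fills.append((b, take))
        need -= take
    if need != 0:
        raise EstimationError("fill plan cannot reach the target dimension")
    return fills


def _build_plan(sizes: list[int], M: int, coeff: dict[int, int],
                seed: int) -> tuple[FillPlan, list[TermKey]]:
    K = len(sizes)
    target = max(sum(sizes[b] for b in T)
                 for T in combinations(range(K), M))
    terms: list[TermKey] = []
    assign: dict[TermKey, list[tuple[int, int]]] = {}

    for m in range(2, M + 1):
        if coeff[m] == 0 and m != M:
            continue
        for T in combinations(range(K), m):
            key = ("T",) + T
            need = target - sum(sizes[b] for b in T)
            assign[key] = _cyclic_fills((max(T) + 1) % K, set(T), need, sizes)
            terms.append(key)
    for b in range(K):
        key = ("B", b, sizes[b])
        assign[key] = _cyclic_fills((b + 1) % K, {b}, target - sizes[b], sizes)
        terms.append(key)
    # closure over truncated-prefix fill elements: each becomes its own term
    pending = True
    while pending:
        pending = False
        used = {("B", b, c) for fills in assign.values() for b, c in fills}
        for b, c in sorted((b, c) for (_, b, c) in used):
            key = ("B", b, c)
            if key not in assign:
                assign[key] = _cyclic_fills((b + 1) % K, {b}, target - c, sizes)
                terms.append(key)
                pending = True
    return FillPlan(target_dim=target, assignments=assign, seed=seed), terms


def _build_replica_plan(sizes: list[int], M: int, coeff: dict[int, int],
                        seed: int) -> tuple[FillPlan, list[TermKey]]:
    """Fallback plan: pad every term with independently permuted copies
    of one anchor mode.  Each fill column contributes the same marginal
    entropy h₀, measured once by the pure-replica reference term ("G",),
    so the cancellation system is always consistent."""
    K = len(sizes)
    target = max(sum(sizes[b] for b in T) for T in combinations(range(K), M))
    terms: list[TermKey] = []
    assign: dict[TermKey, list[tuple[int, int]]] = {}
    for m in range(1, M + 1):
        if coeff[m] == 0:
            continue
        for T in combinations(range(K), m):
            key = ("T",) + T if m > 1 else ("B", T[0], sizes[T[0]])
            need = target - sum(sizes[b] for b in T)
            assign[key] = [(REPLICA, need)] if need else []
            terms.append(key)
    assign[("G",)] = [(REPLICA, target)]
    terms.append(("G",))
    return FillPlan(target_dim=target, assignments=assign, seed=seed,
                    scheme="replica"), terms


def _bookkeeping_matrix(terms: list[TermKey], plan: FillPlan):
    """Matrix mapping term coefficients to total per-basis-element
    weights; basis elements are real subsets, block prefixes, and (for
    the replica scheme) the anchor marginal ("H0",)."""
    basis: dict[TermKey, int] = {}
    for t in terms:
        if t != ("G",):
            basis.setdefault(t, len(basis))
    for fills in plan.assignments.values():
        for b, c in fills:
            key = ("H0",) if b == REPLICA else ("B", b, c)
            basis.setdefault(key, len(basis))
    A = np.zeros((len(basis), len(terms)))
    for j, term in enumerate(terms):
        if term != ("G",):
            A[basis[term], j] += 1.0
        for b, c in plan.assignments[term]:
            if b == REPLICA:
                A[basis[("H0",)], j] += c
            else:
                A[basis[("B", b, c)], j] += 1.0
    return A, basis


# ---------------------------------------------------------------------------
# the expansion
# ---------------------------------------------------------------------------

def _estimator(cfg: EstimatorConfig):
    if cfg.kernel is Kernel.ADAPTIVE_ELLIPSOID:
        def est(B: np.ndarray) -> float:
            return adaptive_kernel_entropy(B, cfg).value
    else:
        def est(B: np.ndarray) -> float:
            return knn_entropy(B, k=cfg.k, jitter_duplicates=cfg.jitter_duplicates,
                               stderr_blocks=0).value
    return est


def mie_entropy(Y, subclusters: list[list[int]], M: int,
                cfg: EstimatorConfig | None = None, seed: int = 0,
                n_fill_draws: int = 1,
                max_dim: int | None = None) -> tuple[EntropyEstimate, MIETerms]:
    """Order-M mutual information expansion over the subclusters (nats).

    ``subclusters`` hold column indices into Y.  Negative intermediate
    terms are never clamped — unbiasedness of the signed sum matters
    more than nonnegativity of components.
    """
    A = np.asarray(getattr(Y, "X", Y), dtype=np.float64)
    cfg = cfg or EstimatorConfig()
    sizes = [len(s) for s in subclusters]
    K = len(subclusters)
    if any(s == 0 for s in sizes):
        raise ParameterError("empty subcluster")
    coeff = derive_coefficients(K, M)
    plan, terms = _build_plan(sizes, M, coeff, seed)
    if max_dim is not None and plan.target_dim > max_dim:
        worst = max(combinations(range(K), M),
                    key=lambda T: sum(sizes[b] for b in T))
        raise ParameterError(
            f"subcluster union {worst} has dimension {plan.target_dim} > "
            f"estimator cap {max_dim}; lower s_max or raise the cap")

    def solve(plan, terms):
        Amat, basis = _bookkeeping_matrix(terms, plan)
        # target: real subsets appear with coeff(|T|), full blocks (the
        # order-1 subsets) with coeff(1), prefixes and the anchor
        # marginal must cancel to 0
        t_vec = np.zeros(len(basis))
        for key, row in basis.items():
            if key[0] == "T":
                t_vec[row] = coeff[len(key) - 1]
            elif key[0] == "B":
                _, b, c = key
                t_vec[row] = coeff[1] if c == sizes[b] else 0.0
        c_sol, *_ = np.linalg.lstsq(Amat, t_vec, rcond=None)
        return c_sol, np.abs(Amat @ c_sol - t_vec).max()

    c_sol, resid = solve(plan, terms)
    if resid > 1e-8:
        # unequal subcluster sizes can make whole-block fills
        # structurally unable to cancel; fall back to anchor replicas
        log.info("block fill plan unsolvable (residual %.2g); using "
                 "replica fills", resid)
        plan, terms = _build_replica_plan(sizes, M, coeff, seed)
        c_sol, resid = solve(plan, terms)
    if resid > 1e-8:
        raise EstimationError(
            "fill-mode bookkeeping is inconsistent for this subcluster "
            f"geometry (residual {resid:.2e}); the signed sum cannot cancel "
            "the fill entropies")

    anchor = subclusters[0][0]

    def real_columns(term: TermKey) -> list[int]:
        if term == ("G",):
            return []
        if term[0] == "T":
            return [c for b in term[1:] for c in subclusters[b]]
        _, b, ncols = term
        return subclusters[b][:ncols]

    inner = EstimatorConfig(**{**cfg.__dict__, "stderr_blocks": 0})
    est = _estimator(inner)

    def evaluate(rows: slice) -> tuple[float, dict[TermKey, float]]:
        B = A[rows]
        nrows = B.shape[0]
        total = 0.0
        values: dict[TermKey, float] = {}
        for j, term in enumerate(terms):
            if abs(c_sol[j]) < 1e-12:
                values[term] = np.nan
                continue
            acc = 0.0
            for draw in range(n_fill_draws):
                cols = [B[:, real_columns(term)]]
                for slot, (b, ncols) in enumerate(plan.assignments[term]):
                    if b == REPLICA:
                        for c in range(ncols):
                            rng = np.random.default_rng(
                                [seed & 0x7FFFFFFF, draw, j, slot, c])
                            cols.append(
                                B[rng.permutation(nrows), anchor][:, None])
                    else:
                        rng = np.random.default_rng(
                            [seed & 0x7FFFFFFF, draw, j, slot])
                        perm = rng.permutation(nrows)
                        cols.append(B[np.ix_(perm, subclusters[b][:ncols])])
                mat = np.hstack(cols)
                assert mat.shape[1] == plan.target_dim, \
                    "fill-dimension consistency violated"
                acc += est(mat)
            values[term] = acc / n_fill_draws
            total += c_sol[j] * values[term]
        return total, values

    value, term_values = evaluate(slice(None))

    stderr = None
    blocks = cfg.stderr_blocks
    n = A.shape[0]
    if blocks >= 2 and n >= 4 * blocks:
        edges = np.linspace(0, n, blocks + 1, dtype=int)
        vals = [evaluate(slice(s, e))[0] for s, e in zip(edges[:-1], edges[1:])]
        stderr = float(np.std(vals, ddof=1) / math.sqrt(blocks))

    record = MIETerms(order=M, coefficients=coeff, plan=plan)
    for j, term in enumerate(terms):
        record.joint_entropies[term] = {
            "value": float(term_values[term]),
            "filled_dim": plan.target_dim,
            "coefficient": float(c_sol[j]),
        }
    d_total = sum(sizes)
    estimate = EntropyEstimate(value=float(value),
                               estimator=f"mie{M}(K={K})", d=d_total,
                               n=n, stderr=stderr)
    return estimate, record


def cluster_entropy(Y, p, cfg: EstimatorConfig | None = None, M: int = 3,
                    seed: int = 0, max_dim: int | None = None) -> list[dict]:
    """Per-cluster entropy contributions for a mode partition.

    Clusters within the size cap get a direct adaptive-kernel estimate;
    oversized clusters go through the order-M expansion over their
    subclusters (with M lowered to the subcluster count when a cluster
    splits into fewer than M parts).
    """
    A = np.asarray(getattr(Y, "X", Y), dtype=np.float64)
    cfg = cfg or EstimatorConfig()
    out = []
    for ci, cluster in enumerate(p.clusters):
        subs = p.subclusters.get(ci)
        if not subs or len(subs) == 1:
            est = adaptive_kernel_entropy(A[:, cluster], cfg)
            out.append({"cluster": ci, "indices": list(cluster),
                        "method": "direct", "estimate": est, "terms": None})
        else:
            m_eff = min(M, len(subs))
            rel = {c: i for i, c in enumerate(cluster)}
            rel_subs = [[rel[c] for c in s] for s in subs]
            est, rec = mie_entropy(A[:, cluster], rel_subs, m_eff, cfg,
                                   seed=seed + 104_729 * ci, max_dim=max_dim)
            out.append({"cluster": ci, "indices": list(cluster),
                        "method": f"mie{m_eff}", "estimate": est, "terms": rec})
    return out
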