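"""End-to-end minimally-coupled-subspace entropy computation.

Stage order: load → superpose → mass-weight → quasi-harmonic baseline →
full correlation analysis → pairwise generalized correlations →
threshold clustering → subdivision of oversized clusters → per-cluster
density estimates (direct, or mutual-information expansion where a
cluster exceeds the size cap) → totals.

Every stage draws its randomness from a seed derived from the master
seed by a fixed per-stage constant (inserting a stage can never
reshuffle a later stage), and reports are serialised with sorted keys
so one master seed yields a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import __version__
from .density import (EntropyEstimate, EstimatorConfig, adaptive_kernel_entropy)
from .ensemble_io import (MASS_WEIGHTED, EnsembleFormat, SampleMatrix,
                          load_ensemble, load_sample_matrix, superpose,
                          to_sample_matrix)
from .exceptions import McsaError, ParameterError
from .fca import fca_transform
from .mie import cluster_entropy
from .partition import (correlation_matrix, residual_coupling_report,
                        subdivide_oversized, threshold_cluster)
from .qh import CLASSICAL, QUANTUM, qh_entropy
from .units import GAS_CONSTANT_R, J_PER_MOL_K, NATS

log = logging.getLogger(__name__)

# fixed per-stage constants of the seed-derivation scheme
_STAGE = {"jitter": 11, "fca": 23, "correlation": 37, "mie": 53, "direct": 71}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(np.random.SeedSequence([int(master), _STAGE[stage]])
               .generate_state(1)[0] % (2**31))


@dataclass
class MCSAConfig:
    """Flat configuration of one pipeline run (mirrors the config file)."""

    input_path: str | None = None
    input_format: str = "matrix_csv"
    topology: str | None = None
    superpose_frames: bool = True
    superpose_reference: int | str = 0
    temperature: float = 300.0
    units: str = NATS
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    fca_tol: float | None = None
    fca_max_sweeps: int = 50
    run_fca: bool = True
    r_c: float = 0.25
    s_max: int = 15
    d_crit: int = 45
    mie_orders: tuple[int, ...] = (2, 3)
    mi_max_samples: int | None = 20_000
    seed: int = 0

    def __post_init__(self):
        for M in self.mie_orders:
            if M not in (2, 3):
                raise ParameterError(f"mie order must be 2 or 3, got {M}")
            if M * self.s_max > self.d_crit:
                raise ParameterError(
                    f"config invariant violated: order {M} × s_max "
                    f"{self.s_max} exceeds d_crit {self.d_crit}; no MIE term "
                    "may exceed the validated estimator dimension")
        if not 0.0 < self.r_c < 1.0:
            raise ParameterError("r_c must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["estimator"] = {k: (v.value if hasattr(v, "value") else v)
                          for k, v in d["estimator"].items()}
        d["mie_orders"] = list(self.mie_orders)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MCSAConfig":
        d = dict(d)
        est = d.pop("estimator", {})
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.estimator = EstimatorConfig(**est) if isinstance(est, dict) else est
        cfg.mie_orders = tuple(cfg.mie_orders)
        return cfg


def _est_dict(e: EntropyEstimate | None) -> dict | None:
    if e is None:
        return None
    return {"value": e.value, "stderr": e.stderr, "units": e.units,
            "estimator": e.estimator, "d": e.d, "n": e.n}


@dataclass
class EntropyReport:
    totals: dict
    per_cluster: list[dict]
    partition: dict
    residual_coupling: dict
    qh: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"totals": self.totals, "per_cluster": self.per_cluster,
                "partition": self.partition,
                "residual_coupling": self.residual_coupling, "qh": self.qh,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          allow_nan=True, default=float)

    def summary_tsv(self) -> str:
        lines = ["quantity\tvalue\tstderr\tunits"]
        for name, t in sorted(self.totals.items()):
            if t is None:
                continue
            err = "" if t.get("stderr") is None else f"{t['stderr']:.6g}"
            lines.append(f"{name}\t{t['value']:.6g}\t{err}\t{t['units']}")
        return "\n".join(lines) + "\n"


def _load_input(cfg: MCSAConfig) -> SampleMatrix:
    fmt = EnsembleFormat(cfg.input_format)
    if fmt is EnsembleFormat.MATRIX_CSV:
        return load_sample_matrix(cfg.input_path)
    e = load_ensemble(cfg.input_path, fmt, topology=cfg.topology)
    if cfg.superpose_frames:
        e = superpose(e, cfg.superpose_reference)
    return to_sample_matrix(e, MASS_WEIGHTED)


def run_mcsa(cfg: MCSAConfig, X: SampleMatrix | np.ndarray | None = None,
             _shared_fca=None, _shared_corr=None) -> EntropyReport:
    """Run the full pipeline; ``X`` bypasses file input.

    Deterministic for a fixed ``cfg.seed``: running twice yields
    byte-identical reports.
    """
    t0 = time.time()
    if X is None:
        if cfg.input_path is None:
            raise ParameterError("config names no input and no matrix was given")
        sm = _load_input(cfg)
    elif isinstance(X, SampleMatrix):
        sm = X
    else:
        sm = SampleMatrix(X=np.asarray(X, dtype=np.float64))
    n, d = sm.X.shape
    scale = GAS_CONSTANT_R if cfg.units == J_PER_MOL_K else 1.0
    est_cfg = cfg.estimator

    def stage(name):
        log.info("[%7.1fs] stage %s", time.time() - t0, name)

    stage("qh")
    qh_c = qh_entropy(sm, T=cfg.temperature, variant=CLASSICAL, units=cfg.units)
    qh_q = qh_entropy(sm, T=cfg.temperature, variant=QUANTUM, units=cfg.units,
                      stderr_blocks=0)

    s_direct = None
    if d <= cfg.d_crit:
        stage("direct")
        s_direct = adaptive_kernel_entropy(sm, est_cfg)

    if _shared_fca is not None:
        transform, Y = _shared_fca
    elif cfg.run_fca and d >= 2:
        stage("fca")
        transform, Y = fca_transform(sm, tol=cfg.fca_tol,
                                     max_sweeps=cfg.fca_max_sweeps,
                                     seed=stage_seed(cfg.seed, "fca"))
    else:
        transform, Y = None, sm

    stage("correlation")
    if _shared_corr is not None:
        R = _shared_corr
    else:
        R = correlation_matrix(Y, seed=stage_seed(cfg.seed, "correlation"),
                               k=est_cfg.k, max_samples=cfg.mi_max_samples)
    part = threshold_cluster(R, cfg.r_c)
    part = subdivide_oversized(part, R, cfg.s_max)
    residual = residual_coupling_report(part, R)

    stage("cluster entropies")
    mie_seed = stage_seed(cfg.seed, "mie")
    per_order = {}
    s_clust_clusters = []
    clust_ok = True
    per_cluster_out = []
    for ci, cluster in enumerate(part.clusters):
        if len(cluster) > cfg.d_crit:
            clust_ok = False
            s_clust_clusters.append(None)
        else:
            est = adaptive_kernel_entropy(Y.X[:, cluster], est_cfg)
            s_clust_clusters.append(est)
            per_cluster_out.append({
                "order": "clust", "cluster": ci, "indices": list(cluster),
                "method": "direct",
                "estimate": _est_dict(est.in_units(cfg.units))})

    for M in sorted(cfg.mie_orders):
        contribs = cluster_entropy(Y, part, est_cfg, M=M, seed=mie_seed,
                                   max_dim=cfg.d_crit)
        tot = sum(c["estimate"].value for c in contribs)
        errs = [c["estimate"].stderr for c in contribs]
        err = (math.sqrt(sum(e * e for e in errs)) if all(e is not None for e in errs)
               else None)
        per_order[M] = (tot, err)
        for c in contribs:
            per_cluster_out.append({
                "order": M, "cluster": c["cluster"], "indices": c["indices"],
                "method": c["method"],
                "estimate": _est_dict(c["estimate"].in_units(cfg.units)),
            })

    def tot_dict(val, err, tag, dd=d):
        return {"value": val * scale, "stderr": None if err is None else err * scale,
                "units": cfg.units, "estimator": tag, "d": dd, "n": n}

    s_clust_val = None
    if clust_ok:
        vals = [c.value for c in s_clust_clusters]
        errs = [c.stderr for c in s_clust_clusters]
        err = (math.sqrt(sum(e * e for e in errs))
               if all(e is not None for e in errs) else None)
        s_clust_val = tot_dict(sum(vals), err, "clustered_direct")

    totals = {
        "S_QH_classical": {"value": qh_c.S_classical, "stderr": qh_c.stderr,
                           "units": cfg.units, "estimator": "qh_classical",
                           "d": d, "n": n},
        "S_QH_quantum": {"value": qh_q.S_quantum, "stderr": None,
                         "units": cfg.units, "estimator": "qh_quantum",
                         "d": d, "n": n},
        "S_direct": (None if s_direct is None
                     else _est_dict(s_direct.in_units(cfg.units))),
        "S_clust": s_clust_val,
    }
    for M, (tot, err) in per_order.items():
        totals[f"S_MIE{M}"] = tot_dict(tot, err, f"mie{M}")

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    provenance = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {k: stage_seed(cfg.seed, k) for k in _STAGE},
        "n_frames": n, "dimension": d,
        "fca_sweeps": None if transform is None else transform.sweeps,
        "fca_objective_trace": (None if transform is None
                                else [round(v, 12) for v in transform.objective_trace]),
    }
    report = EntropyReport(
        totals=totals, per_cluster=per_cluster_out,
        partition={"clusters": part.clusters, "threshold": part.threshold,
                   "s_max": part.s_max,
                   "subclusters": {str(k): v for k, v in part.subclusters.items()}},
        residual_coupling=residual, qh={
            "eigenvalues": [float(v) for v in qh_c.eigenvalues],
            "discarded": qh_c.discarded, "T": cfg.temperature},
        provenance=provenance)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def compare_thresholds(cfg: MCSAConfig, r_c_list, X=None):
    """Partition + entropy stages at several clustering thresholds on one
    shared FCA output; returns a row per threshold plus the spread."""
    r_c_list = list(r_c_list)
    if len(r_c_list) < 2:
        raise ParameterError("need at least 2 thresholds to compare")
    if X is None:
        sm = _load_input(cfg)
    elif isinstance(X, SampleMatrix):
        sm = X
    else:
        sm = SampleMatrix(X=np.asarray(X, dtype=np.float64))
    shared = None
    Y = sm
    if cfg.run_fca and sm.d >= 2:
        shared = fca_transform(sm, tol=cfg.fca_tol,
                               max_sweeps=cfg.fca_max_sweeps,
                               seed=stage_seed(cfg.seed, "fca"))
        Y = shared[1]
    R = correlation_matrix(Y, seed=stage_seed(cfg.seed, "correlation"),
                           k=cfg.estimator.k, max_samples=cfg.mi_max_samples)
    rows = []
    for r_c in r_c_list:
        sub = replace(cfg, r_c=r_c)
        rep = run_mcsa(sub, X=sm, _shared_fca=shared, _shared_corr=R)
        row = {"r_c": r_c}
        for name, t in rep.totals.items():
            row[name] = None if t is None else t["value"]
            row[name + "_stderr"] = None if t is None else t["stderr"]
        rows.append(row)
    spread = {}
    for name in ("S_clust", "S_MIE2", "S_MIE3"):
        vals = [r[name] for r in rows if r.get(name) is not None]
        if len(vals) == len(rows):
            spread[name] = max(vals) - min(vals)
    return {"rows": rows, "spread": spread}
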