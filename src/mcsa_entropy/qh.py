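"""Quasi-harmonic baseline entropies.

The quasi-harmonic (QH) approximation fits a single multivariate
Gaussian to the configurational density through the mass-weighted
covariance matrix and reads the entropy off its eigenvalue spectrum —
an upper bound on the true configurational entropy (the Gaussian
maximises entropy at fixed covariance), exceeded whenever the density
is anharmonic, coupled beyond second order, or multi-minima.

Two variants:

* ``classical_gaussian`` — the differential entropy of the fitted
  Gaussian, S = R · ½ Σ ln(2πe λ_i) over retained eigenvalues.  This is
  the convention every cross-estimator comparison in this package uses
  (QH vs direct vs clustered vs MIE are all differential
  configurational entropies in mass-weighted coordinates).
* ``quantum_oscillator`` — each eigenvalue λ_i (nm²·u) maps to an
  oscillator of frequency ω_i = sqrt(k_B T/λ_i); with α_i = ħω_i/k_B T,
  S = R Σ [α/(e^α − 1) − ln(1 − e^{−α})].  This carries its own
  absolute (momentum-inclusive) normalisation and is reported
  separately, never mixed into MCSA totals.

Near-zero eigenvalues (rigid-body remnants, constraints) are discarded
by a relative floor instead of explicit 6-mode projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateEnsembleError, ParameterError
from .units import (GAS_CONSTANT_R, HBAR_KJ_PS_PER_MOL, J_PER_MOL_K,
                    KB_KJ_PER_MOL_K, NATS)

log = logging.getLogger(__name__)

_LN_2PIE = math.log(2.0 * math.pi * math.e)

CLASSICAL = "classical_gaussian"
QUANTUM = "quantum_oscillator"

EIGENVALUE_FLOOR = 1e-12   # relative to the largest eigenvalue


@dataclass
class QHResult:
    covariance: np.ndarray          # d × d, nm²·u for mass-weighted input
    eigenvalues: np.ndarray         # sorted descending, retained only
    S_classical: float | None       # J/(mol K) (or nats, see units)
    S_quantum: float | None
    T: float
    discarded: int
    units: str = J_PER_MOL_K
    stderr: float | None = None


def _spectrum(X: np.ndarray, floor: float):
    n, d = X.shape
    C = np.atleast_2d(np.cov(X, rowvar=False))
    evals = np.linalg.eigvalsh(C)[::-1]
    cut = floor * max(evals[0], 0.0)
    keep = evals[evals > cut]
    dropped = evals[evals <= cut]
    if keep.size == 0:
        raise DegenerateEnsembleError(
            "all covariance eigenvalues fall below the floor; the ensemble "
            "has no resolvable configurational spread")
    if dropped.size:
        log.info("discarded %d eigenvalue(s) below floor %.3g: %s",
                 dropped.size, cut, np.array2string(dropped, precision=3))
    return C, keep, dropped.size


def classical_entropy_nats(eigenvalues: np.ndarray) -> float:
    return float(0.5 * (np.log(eigenvalues) + _LN_2PIE).sum())


def quantum_entropy_nats(eigenvalues: np.ndarray, T: float) -> float:
    kbt = KB_KJ_PER_MOL_K * T
    omega = np.sqrt(kbt / eigenvalues)          # 1/ps, λ in nm²·u
    alpha = HBAR_KJ_PS_PER_MOL * omega / kbt
    with np.errstate(over="ignore"):
        s = alpha / np.expm1(alpha) - np.log1p(-np.exp(-alpha))
    return float(np.where(np.isfinite(s), s, 0.0).sum())


def qh_entropy(X, T: float = 300.0, variant: str = CLASSICAL,
               units: str = J_PER_MOL_K, floor: float = EIGENVALUE_FLOOR,
               stderr_blocks: int = 5) -> QHResult:
    """Quasi-harmonic entropy from the sample covariance spectrum.

    ``X`` is the (mass-weighted, for the quantum variant) sample matrix.
    Returns the requested variant; the other total is left None.
    """
    if variant not in (CLASSICAL, QUANTUM):
        raise ParameterError(f"unknown QH variant {variant!r}")
    if T <= 0:
        raise ParameterError("temperature must be positive")
    A = np.asarray(getattr(X, "X", X), dtype=np.float64)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ParameterError("need an (n >= 2, d) sample matrix")
    C, keep, dropped = _spectrum(A, floor)

    def total(B: np.ndarray) -> float:
        _, ev, _ = _spectrum(B, floor)
        nats = (classical_entropy_nats(ev) if variant == CLASSICAL
                else quantum_entropy_nats(ev, T))
        return nats * (GAS_CONSTANT_R if units == J_PER_MOL_K else 1.0)

    nats = (classical_entropy_nats(keep) if variant == CLASSICAL
            else quantum_entropy_nats(keep, T))
    scale = GAS_CONSTANT_R if units == J_PER_MOL_K else 1.0
    value = nats * scale

    stderr = None
    n = A.shape[0]
    if stderr_blocks >= 2 and n >= 4 * stderr_blocks:
        edges = np.linspace(0, n, stderr_blocks + 1, dtype=int)
        vals = [total(A[s:e]) for s, e in zip(edges[:-1], edges[1:])]
        stderr = float(np.std(vals, ddof=1) / math.sqrt(stderr_blocks))

    return QHResult(covariance=C, eigenvalues=keep,
                    S_classical=value if variant == CLASSICAL else None,
                    S_quantum=value if variant == QUANTUM else None,
                    T=T, discarded=dropped, units=units, stderr=stderr)


def harmonic_reference_entropy(k_restraint: float, masses,
                               T: float = 300.0) -> dict:
    """Analytic entropy of 3N independent harmonic oscillators.

    The reference endpoint of a thermodynamic-integration route: every
    atom sits in an isotropic harmonic well of force constant
    ``k_restraint`` (kJ mol⁻¹ nm⁻²).  Per mode, classically,

        S/R = 1 − ln(ħ ω / k_B T),   ω = sqrt(k/m).

    Returns the total (kinetic + configurational, with its ħ-dependent
    absolute normalisation) and the configurational part
    R·½ ln(2πe λ) with λ = m k_B T / k — the term comparable to the
    classical QH entropy of a sampled harmonic ensemble.  Units
    J/(mol K).
    """
    masses = np.asarray(masses, dtype=np.float64)
    if k_restraint <= 0 or np.any(masses <= 0) or T <= 0:
        raise ParameterError("force constant, masses and T must be positive")
    kbt = KB_KJ_PER_MOL_K * T
    omega = np.sqrt(k_restraint / masses)               # 1/ps
    alpha = HBAR_KJ_PS_PER_MOL * omega / kbt
    per_atom_total = 3.0 * (1.0 - np.log(alpha))
    lam = masses * kbt / k_restraint                    # nm²·u
    per_atom_conf = 3.0 * 0.5 * (_LN_2PIE + np.log(lam))
    return {
        "S_total": float(per_atom_total.sum() * GAS_CONSTANT_R),
        "S_configurational": float(per_atom_conf.sum() * GAS_CONSTANT_R),
        "modes": int(3 * masses.size),
        "T": T,
        "units": J_PER_MOL_K,
    }
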