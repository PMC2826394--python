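"""Ensemble input, superposition, and mass weighting.

Reads a conformational ensemble (multi-model PDB, binary trajectory +
topology, or a plain numeric matrix), removes rigid-body motion by
mass-weighted least-squares (Kabsch) superposition, and flattens it
into the frames × d mass-weighted sample matrix on which all entropy
estimators operate.

Conventions (fixed and relied upon by the rest of the pipeline):

* coordinates in nm, masses in u;
* flattening is atom-major with xyz contiguous per atom, column
  3*i + c = sqrt(m_i) * coord(atom i, axis c) under mass weighting;
* superposition fits every frame onto the first frame by default, or
  onto the iterated ensemble mean (two passes) with ``reference="mean"``;
* the six rigid-body degrees of freedom are not projected out — the
  near-zero covariance eigenvalues they leave behind are handled by the
  eigenvalue floor in the quasi-harmonic module;
* plain-matrix input is taken as preprocessed: unit masses, no
  superposition, weighting "plain".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import (FormatError, InsufficientDataError, ParameterError,
                         SuperpositionError)

log = logging.getLogger(__name__)

MASS_WEIGHTED = "mass_weighted"
PLAIN = "plain"


class EnsembleFormat(str, Enum):
    PDB_MULTIMODEL = "pdb_multimodel"
    TRAJECTORY = "trajectory+topology"
    MATRIX_CSV = "matrix_csv"


@dataclass
class Ensemble:
    """frames × atoms × 3 coordinates (nm) with per-atom masses (u)."""

    coords: np.ndarray
    masses: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise InsufficientDataError(
                f"an ensemble needs >= 2 frames, got {self.coords.shape[0]}")
        if self.masses.shape != (self.coords.shape[1],):
            raise ParameterError("masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ParameterError("all masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("coords contain non-finite values")

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    @property
    def atom_count(self) -> int:
        return self.coords.shape[1]


@dataclass
class SampleMatrix:
    """frames × d matrix the estimators operate on (nm·u^½ when
    mass-weighted)."""

    X: np.ndarray
    weighting: str = PLAIN
    masses: np.ndarray | None = None   # per-atom, kept for round trips

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ParameterError("sample matrix must be 2-D (frames x d)")
        if self.weighting not in (MASS_WEIGHTED, PLAIN):
            raise ParameterError(f"unknown weighting {self.weighting!r}")
        n, d = self.X.shape
        if n < 10 * d:
            log.warning("sample matrix has n=%d frames for d=%d coordinates "
                        "(< 10 per dimension); estimates may be noisy", n, d)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_ensemble(path: str, format: EnsembleFormat | str,
                  topology: str | None = None) -> Ensemble:
    """Read an ensemble from disk.

    ``matrix_csv`` returns a degenerate Ensemble whose "atoms" are the raw
    columns grouped in triples only if d % 3 == 0; use
    :func:`load_sample_matrix` to feed a matrix straight to the estimators.
    """
    fmt = EnsembleFormat(format)
    if fmt is EnsembleFormat.MATRIX_CSV:
        sm = load_sample_matrix(path)
        n, d = sm.X.shape
        if d % 3 != 0:
            raise FormatError(
                f"{path}: {d} columns cannot be grouped into atoms of 3 "
                "coordinates; load it with load_sample_matrix instead")
        coords = sm.X.reshape(n, d // 3, 3)
        return Ensemble(coords=coords, masses=np.ones(d // 3))

    import mdtraj as md  # deferred: heavy import

    try:
        if fmt is EnsembleFormat.PDB_MULTIMODEL:
            traj = md.load_pdb(path)
        else:
            if topology is None:
                raise ParameterError(
                    "trajectory input requires a topology file for atom masses")
            traj = md.load(path, top=topology)
    except (ParameterError, InsufficientDataError):
        raise
    except Exception as err:
        raise FormatError(f"could not parse {path} as {fmt.value}: {err}") from err

    if traj.n_frames < 2:
        raise InsufficientDataError(
            f"{path} holds {traj.n_frames} frame(s); an ensemble needs >= 2")
    masses = np.array([a.element.mass for a in traj.topology.atoms])
    labels = [f"{a.residue.name}{a.residue.resSeq}:{a.name}"
              for a in traj.topology.atoms]
    log.info("loaded %s: %d frames, %d atoms", path, traj.n_frames, traj.n_atoms)
    return Ensemble(coords=np.asarray(traj.xyz, dtype=np.float64),
                    masses=masses, labels=labels)


def load_sample_matrix(path: str) -> SampleMatrix:
    """Plain CSV/TSV numeric matrix, rows = frames; unit masses, no
    superposition or mass weighting (assumed preprocessed)."""
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#")
        X = df.to_numpy(dtype=np.float64)
    except Exception as err:
        raise FormatError(f"could not parse {path} as a numeric matrix: "
                          f"{err}") from err
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError(
            f"{path}: need a 2-D matrix with >= 2 rows, got shape {X.shape}")
    log.info("loaded %s: %d frames x %d columns", path, *X.shape)
    return SampleMatrix(X=X, weighting=PLAIN)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation matrix minimising weighted RMSD of P onto Q (both centred)."""
    H = (w[:, None] * P).T @ Q
    U, s, Vt = np.linalg.svd(H)
    if s[-1] <= 1e-12 * max(s[0], 1e-300):
        raise SuperpositionError(
            "degenerate reference geometry (collinear or < 3 atoms); "
            "cannot determine a unique rotation")
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    return Vt.T @ D @ U.T


def _fit_frames(coords: np.ndarray, ref: np.ndarray, w: np.ndarray) -> np.ndarray:
    wsum = w.sum()
    ref_c = ref - (w[:, None] * ref).sum(0) / wsum
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        P = coords[f]
        Pc = P - (w[:, None] * P).sum(0) / wsum
        R = _kabsch(Pc, ref_c, w)
        out[f] = Pc @ R.T
    return out


def superpose(e: Ensemble, reference: int | str = 0, passes: int = 2) -> Ensemble:
    """Mass-weighted least-squares fit of every frame.

    ``reference`` is a frame index (default: first frame) or ``"mean"``
    for an iterated fit to the ensemble mean (``passes`` rounds).
    The returned ensemble has identical per-frame internal geometry;
    frames are centred at the weighted origin.
    """
    if e.atom_count < 3:
        raise SuperpositionError("superposition needs >= 3 atoms")
    w = e.masses / e.masses.sum()
    if reference == "mean":
        fitted = _fit_frames(e.coords, e.coords[0], w)
        for _ in range(max(1, passes) - 1):
            fitted = _fit_frames(fitted, fitted.mean(axis=0), w)
    else:
        reference = int(reference)
        if not 0 <= reference < e.frame_count:
            raise ParameterError(
                f"reference frame {reference} out of range 0..{e.frame_count - 1}")
        fitted = _fit_frames(e.coords, e.coords[reference], w)
    return Ensemble(coords=fitted, masses=e.masses, labels=e.labels)


def mass_weighted_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    w = masses / masses.sum()
    return float(np.sqrt((w[:, None] * (a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------

def to_sample_matrix(e: Ensemble, weighting: str = MASS_WEIGHTED) -> SampleMatrix:
    """Flatten to frames × 3·atoms; column 3i+c = sqrt(m_i)·coord(i, c)."""
    if weighting not in (MASS_WEIGHTED, PLAIN):
        raise ParameterError(f"unknown weighting {weighting!r}")
    n = e.frame_count
    X = e.coords.reshape(n, -1).copy()
    if weighting == MASS_WEIGHTED:
        X *= np.sqrt(np.repeat(e.masses, 3))[None, :]
    return SampleMatrix(X=X, weighting=weighting, masses=e.masses.copy())


def from_sample_matrix(sm: SampleMatrix) -> np.ndarray:
    """Inverse of :func:`to_sample_matrix`: frames × atoms × 3 coordinates."""
    if sm.d % 3 != 0:
        raise ParameterError("sample matrix dimension is not a multiple of 3")
    X = sm.X.copy()
    if sm.weighting == MASS_WEIGHTED:
        if sm.masses is None:
            raise ParameterError("mass-weighted matrix lacks stored masses")
        X /= np.sqrt(np.repeat(sm.masses, 3))[None, :]
    return X.reshape(sm.n, sm.d // 3, 3)
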