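"""Shared fixtures: programmatically generated ensembles and file inputs."""

import numpy as np
import pytest


def write_multimodel_pdb(path, frames, names=None):
    """Write frames (list of (atoms, 3) arrays, nm) as a multi-model PDB
    (coordinates in Å, hence the factor 10)."""
    atoms = len(frames[0])
    names = names or (["N", "CA", "C", "O", "CB"] * atoms)[:atoms]
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(np.asarray(coords) * 10.0):
                fh.write(
                    "ATOM  {:5d} {:^4s} ALA A   1    {:8.3f}{:8.3f}{:8.3f}"
                    "  1.00  0.00          {:>2s}\n".format(
                        i + 1, names[i], x, y, z, names[i][0]))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


@pytest.fixture
def pdb_3x4(tmp_path):
    """3-model PDB of a 4-atom fragment with non-degenerate geometry."""
    rng = np.random.default_rng(11)
    base = rng.standard_normal((4, 3)) * 0.1
    frames = [base, base + 0.01 * rng.standard_normal((4, 3)),
              base + 0.01 * rng.standard_normal((4, 3))]
    return write_multimodel_pdb(tmp_path / "tiny.pdb", frames,
                                names=["N", "CA", "C", "O"])


@pytest.fixture
def rigid_ensemble():
    """5-atom structure under pure rigid-body motion (identical geometry)."""
    from mcsa_entropy import Ensemble

    rng = np.random.default_rng(3)
    base = rng.standard_normal((5, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    frames = np.array([base, base @ Rz.T + [1.0, 2.0, 3.0],
                       (base @ Rz.T @ Rz.T) - [0.5, 0.0, 1.0]])
    return Ensemble(coords=frames, masses=np.array([12.0, 1.0, 16.0, 14.0, 12.0]))


def brute_force_knn_entropy(X, k):
    """Independent all-pairs reference implementation of the
    digamma-corrected k-NN entropy (explicit loops, float64)."""
    from scipy.special import digamma, gammaln

    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    ln_r = np.empty(n)
    for i in range(n):
        dists = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        dists[i] = np.inf
        ln_r[i] = np.log(np.sort(dists)[k - 1])
    ln_vd = (d / 2.0) * np.log(np.pi) - gammaln(d / 2.0 + 1.0)
    return float(digamma(n) - digamma(k) + ln_vd + (d / n) * ln_r.sum())
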