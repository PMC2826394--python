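# mcsa-entropy

Absolute configurational entropies of macromolecules from structure
ensembles, via minimally coupled subspaces.

## The problem

The configurational entropy S = −R ∫ p(x) ln p(x) dx of a biomolecule —
the solute part of the entropy that drives ligand binding and folding —
must be estimated from a finite conformational ensemble (an MD
trajectory, a multi-model PDB) whose density p lives in hundreds of
dimensions.  The standard quasi-harmonic (QH) estimate fits one
multivariate Gaussian through the mass-weighted covariance and
therefore *overestimates* S whenever the landscape is anharmonic,
nonlinearly coupled, or multi-minima.  Direct nonparametric density
estimation fixes that, but the curse of dimensionality confines it to a
few tens of dimensions.

This package implements the minimally coupled subspace approach (MCSA),
which combines three building blocks so that nonparametric estimation
becomes applicable to large systems:

1. **Adaptive anisotropic kernel density estimation** — a
   Kozachenko–Leonenko k-nearest-neighbour entropy estimator,
   Ĥ = ψ(n) − ψ(k) + ln V_d + (d/n) Σᵢ ln ρᵢ, whose metric adapts to a
   unit-determinant local-covariance shape (reducing exactly to plain
   k-NN in the isotropic limit);
2. **Full Correlation Analysis (FCA)** — an orthonormal, hence
   entropy-invariant, transform minimising the total mutual information
   Σᵢ H(yᵢ) − H(y), after which modes are clustered into minimally
   coupled subspaces by the generalized correlation coefficient
   r = √(1 − e^(−2I)), so the density approximately factorises over
   clusters small enough to estimate directly;
3. **Mutual information expansions (MIE)** — for clusters that remain
   oversized, an inclusion–exclusion expansion of the cluster entropy
   over subclusters, truncated at order 2 or 3, with *fill modes*
   (row-permuted block copies) padding every term to one common
   dimension so the dimension-dependent estimator bias cancels in the
   signed sum.

A synthetic-ensemble module generates test distributions with exactly
known entropies (gaussians, block gaussians, rotated uniforms, Gaussian
mixtures, a bimodal double-well chain), so every stage is verifiable
against closed forms or quadrature — no trajectories required.

## Worked example

A 12-dimensional double-well chain (first coordinate hops between two
wells, the rest follow by damped coupling) is the smallest system that
shows the full story: its exact entropy is 9.399 nats (chain-rule
quadrature), while a Gaussian with its exact covariance would claim
9.861 nats — a 0.462-nat multi-minima gap.

```python
from mcsa_entropy import (MCSAConfig, SyntheticSpec, oracle_entropy,
                          run_mcsa, sample)

spec = SyntheticSpec(kind="double_well_chain", n=50_000, seed=42,
                     params={"d": 12})
cfg = MCSAConfig(seed=7, s_max=4, mie_orders=(2, 3), units="nats",
                 run_fca=False)   # raw coordinates keep the chain coupled
report = run_mcsa(cfg, X=sample(spec))
for name in ("S_QH_classical", "S_clust", "S_MIE3", "S_MIE2"):
    t = report.totals[name]
    print(f"{name:16s} {t['value']:7.3f} ± {t['stderr']:.3f} nats")
print(f"{'oracle':16s} {oracle_entropy(spec).value:7.3f} nats")
```

prints

```
S_QH_classical     9.863 ± 0.011 nats
S_clust            9.669 ± 0.011 nats
S_MIE3             9.669 ± 0.011 nats
S_MIE2             9.331 ± 0.018 nats
oracle             9.399 nats
```

The quasi-harmonic estimate overshoots the true value by the predicted
multi-minima gap; clustering with direct kernel estimation removes
about half of that; the second-order expansion undershoots while the
third-order expansion bounds from above — the characteristic ordering
S_MIE2 ≤ S_MIE3 ≤ S_clust ≤ S_QH.

The same pipeline runs from the shell on files:

```bash
mcsa-entropy synth --kind double_well_chain --n 50000 --seed 42 \
    --params '{"d": 12}' --out chain.csv     # + chain.json oracle sidecar
mcsa-entropy run --config config.yaml --out report.json
mcsa-entropy qh chain.csv
mcsa-entropy fca chain.csv --out W.csv
mcsa-entropy compare-thresholds --config config.yaml --thresholds 0.15,0.4
```

where `config.yaml` holds flat `MCSAConfig` keys
(`input_path: chain.csv`, `input_format: matrix_csv`, `r_c: 0.25`,
`s_max: 4`, …).  PDB/XTC/DCD inputs are superposed (mass-weighted
Kabsch) and mass-weighted automatically.

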