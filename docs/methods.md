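# Methods

## The quantity

The configurational entropy of a macromolecule is

S = −R ∫ p(x) ln p(x) dx,

with p the equilibrium density over the internal configurational
coordinates x and R the molar gas constant.  All estimators in this
package work on the frames × d sample matrix of mass-weighted Cartesian
coordinates (columns √m_i · x_{i,c}, units nm·u^½) after rigid-body
motion has been removed by superposition.  Internally everything is a
dimensionless differential entropy in nats; reports convert by R
(8.31446 J mol⁻¹ K⁻¹ per nat) on request.  Because differential
entropies shift under a change of length unit, only *differences and
comparisons within one convention* are meaningful, and every
cross-estimator comparison the package makes (quasi-harmonic vs direct
vs clustered vs expansion totals) uses this one convention.  The
quantum-oscillator quasi-harmonic variant and the analytic harmonic
reference carry their own absolute normalisations (ħ-dependent) and are
reported separately, never mixed into the other totals.

## Pipeline

1. **Input** — multi-model PDB or binary trajectory + topology (via
   mdtraj), or a preprocessed numeric matrix.  Frames are superposed by
   mass-weighted Kabsch fit onto the first frame (option: two-pass fit
   to the ensemble mean).  The six rigid-body degrees of freedom are not
   projected out; the near-zero covariance eigenvalues they leave are
   removed by a relative floor (1e-12 × largest) in the quasi-harmonic
   stage.
2. **Quasi-harmonic baseline** — Gaussian fit through the covariance
   spectrum; an upper bound on S, exceeded most severely for
   multi-minima densities.
3. **Full correlation analysis (FCA)** — orthonormal W minimising
   Σ_i Ĥ(y_i) (equivalently, total mutual information, since the joint
   entropy is invariant).  Optimised by PCA initialisation and Jacobi
   sweeps with a 3° grid + golden-section angle search per mode pair;
   only improving rotations are accepted, so the objective trace is
   non-increasing by construction.  Inner-loop marginals use a
   histogram estimator (Rice rule, ≥16 bins, analytic ln-bin-width
   correction) for speed; reported mutual informations use k-NN
   estimates.
4. **Clustering** — pairwise mutual informations are mapped to the
   generalized correlation r = √(1 − e^{−2I}) (= |ρ| for bivariate
   gaussians) and modes are clustered by connected components of the
   r > r_c graph; clusters larger than s_max are subdivided by
   constrained average-linkage agglomeration.
5. **Per-cluster entropies** — direct adaptive-kernel estimates for
   clusters within the size cap; mutual-information expansion (order 2
   or 3) over the subclusters of oversized ones; totals are sums with
   standard errors combined in quadrature across clusters.

## Density estimators

`knn_entropy` is the Kozachenko–Leonenko estimator
Ĥ = ψ(n) − ψ(k) + ln V_d + (d/n) Σ ln R_i(k).  `adaptive_kernel_entropy`
replaces the Euclidean metric by a per-point unit-determinant shape
matrix Λ_i (an adaptive anisotropic ellipsoidal kernel); with Λ_i = I it
reduces to `knn_entropy` exactly, which is asserted bit-for-bit in the
tests.

**Shape construction.**  The sample covariance of the local_k nearest
neighbours is (a) shrunk toward its isotropic part with a Ledoit–Wolf
intensity, and (b) blended toward the global covariance with weight
γ = min(1, d²/local_k), then normalised to unit determinant.  The blend
reflects estimator reliability: a d×d covariance needs of order d²
samples, and in high dimension the k-NN ball is so wide that "local"
shape information does not exist — γ → 1 turns the estimator into k-NN
on globally whitened data, which is also the fast path (one whitening,
one neighbour search).  Because the shape field varies on the local_k
scale, shapes are evaluated on a landmark subgrid of that resolution
(stride local_k/256) and looked up by nearest landmark.

**Defaults and why.**  k = 5 (NN estimators have minimal bias at small
k; k=1 is noisier without less bias here).  local_k = max(4(d+1),
8192/d²): large neighbourhoods in low d where locality is resolvable,
shrinking with dimension so that γ reaches 1 by d ≈ 10.  The
Mahalanobis neighbour search scans a pool of the 256 (≥ 16k) nearest
Euclidean candidates.  ε-regularisation 1e-10 × trace/d guards exact
degeneracies; duplicate frames fail loudly by default with an opt-in
deterministic jitter (1e-8 × column stdev), because silent jitter hides
degenerate inputs.

**Known bias, and an honest limit.**  At d = 45 and n = 5·10⁴ the k-th
neighbour ellipsoid of a unit-covariance gaussian has radius ≈ 3.3 σ,
so the locally-uniform-density assumption behind the k-NN form fails
and *any* estimator of this family overestimates by ≈ +6–7 % there
(measured on block gaussians; whitening removes the anisotropy penalty
but not this intrinsic term, and the bias moves only as (k/n)^{2/d}).
Recovering high-dimensional accuracy therefore relies on the pipeline
(FCA + clustering keeps direct estimates low-dimensional), not on the
raw estimator.  Crucially, the *fill-mode* machinery (below) makes this
dimension-dependent bias cancel inside expansions.

**Standard errors** use the batch-means method: the estimator is
re-run on 5 contiguous frame blocks and the spread of the block
estimates (sd/√5) approximates the standard error of the pooled
estimate, since estimator variance scales as 1/n.  Contiguous blocks
respect trajectory autocorrelation.  (A delete-block jackknife gives
similar numbers at ~5× the cost of the batch route.)

## Mutual information expansion

For K subclusters at truncation order M, expanding over entropy rather
than correlation terms gives S_MIE(M) = Σ_m coeff(m) Σ_{|T|=m} S(T)
with coefficients fixed by inclusion–exclusion (derived symbolically
and cross-checked against a brute-force expansion for K ≤ 6).
Estimating S(T) terms at their native dimensions would bias the signed
sum, because k-NN-family bias grows with dimension.  Two devices fix
this:

* **fill modes** — appending a subcluster block after one joint row
  permutation preserves its internal density but destroys all
  cross-correlation;
* **consistent dimensions** — every term is padded with fill blocks
  (assigned cyclically, truncating the last block when needed) to the
  common dimension of the largest order-M union, so all estimates share
  dimension, sample size, and bias.

A filled estimate equals the real term's entropy plus its fill blocks'
entropies.  The coefficients applied to the filled estimates are
re-derived by solving the linear system that cancels every fill
contribution while reproducing the inclusion–exclusion weights on the
real terms (truncated fill prefixes enter as auxiliary estimated
terms); the solve residual is asserted to vanish before any result is
returned, which *proves* the bookkeeping for the given geometry instead
of trusting a transcribed formula.  For equal-size subclusters the
solution reduces to the textbook coefficients.  Negative intermediate
terms are deliberately not clamped — unbiasedness of the signed sum
matters more than nonnegativity of its components (the pairwise-MI
*diagnostic* used for clustering does clamp, and logs the raw value).

## Synthetic ensembles and what they do (not) show

The generator produces gaussians and block gaussians (harmonic and
block-correlated regimes, closed-form entropies), rotated uniforms
(bounded non-Gaussian sources for the FCA unmixing check, closed form),
gaussian mixtures (multi-minima, quadrature oracle for d ≤ 3), and a
double-well chain: x₁ ~ ½N(−a,σ²)+½N(a,σ²), x_j = c·x_{j−1} + N(0,τ²),
defaults d = 12, a = 1.5, σ = 0.5, c = 0.8, τ = 0.5 — bimodal,
correlated along the chain, with exact covariance by recursion and an
exact entropy via the chain rule (only the bimodal first marginal needs
1-D quadrature; all conditionals are Gaussian).  Defaults were chosen
once to give strong but not pathological coupling (adjacent
generalized correlations ≈ 0.9) and a clear multi-minima QH gap
(≈ 0.46 nats).

These ensembles have i.i.d. frames and exactly known densities; they
validate the estimators, the transform, the clustering and the
expansion algebra.  They do not emulate trajectory autocorrelation,
rugged many-minima landscapes, or solvent coupling, so passing tests
bound algorithmic correctness, not force-field realism.

On the chain system FCA (correctly) removes nearly all linear coupling,
after which clustering finds almost nothing to group — the expansion
machinery would sit idle.  The ordering study (expansion orders vs
clustered vs quasi-harmonic totals) therefore runs with FCA disabled so
the clustering and expansion stages face the full coupling; this is a
property of that test system, not of real ensembles.

## Numerical choices

* Neighbour searches: exact all-pairs float64 below n = 2048 (the
  reference path for bit-exactness tests), k-d tree for d ≤ 10, blocked
  float32 matrix products above (kept distances re-refined in float64;
  the float32 pass costs ~1e-7 relative distance error, orders below
  estimator noise at those n).
* Pairwise-MI matrices for clustering cap the rows used per pair at
  20,000 (deterministic prefix) — clustering needs r to ±0.03, not the
  full trajectory.
* FCA angle ties break toward smaller θ; the [0°, 90°) range suffices
  by the symmetry of a pair rotation.  tol defaults to 0.001·d nats per
  sweep, max_sweeps 50.
* Clustering presets r_c = 0.25 (default), 0.4 ("hi"), 0.15 ("lo");
  s_max = 15 with the configuration invariant M·s_max ≤ d_crit
  (d_crit = 45) so no expansion term exceeds the dimension the kernel
  estimator is exercised at.
* Per-stage seeds derive from the master seed via fixed per-stage
  constants (SeedSequence([master, constant])), so adding a stage never
  reshuffles another stage's randomness; reports serialise with sorted
  keys and are byte-identical under a fixed master seed.
* The acceptance script runs the chain pipeline at n = 20,000 (its
  totals stabilise well below that; the test suite exercises the same
  system at n = 50,000).

## Known limitations

* Cartesian mass-weighted coordinates only; no internal-coordinate
  (dihedral) transforms, solvent entropy, or permutation reduction.
* The direct estimator's high-dimensional bias (+6–7 % at d = 45,
  n = 5·10⁴) is intrinsic to the k-NN family; results in tens of
  dimensions should lean on the clustered/expansion route.
* Truncation orders M ≥ 4 are not supported (combinatorial explosion).
* FCA explores only orthonormal linear transforms.
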