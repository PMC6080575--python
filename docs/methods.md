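# Methods

## Overview

`devmeta` analyzes an ordered sequence of non-negative symmetric networks
— in the motivating application, inter-regional cortical-thickness
correlation networks for ages 3–20 — as a single object: a connection ×
time matrix **X** whose columns are the vectorized strict upper triangles
of the per-age networks. The pipeline has four parts: network
construction, stage identification, stage-evolving factorization, and
connection characterization, with split-half reproducibility as the
validation layer.

## Network construction

Per age, a subjects × ROIs table of a regional morphometric measure is
confound-regressed ROI-by-ROI with ordinary least squares (intercept +
confounds; categorical confounds dummy-coded against a first-level
reference; constant covariates are dropped since they duplicate the
intercept, reducing the regression to mean removal). Residuals are
correlated across subjects and absolute values taken; the diagonal is
zeroed and excluded from vectorization, so an N-node network contributes
M = N(N−1)/2 weights in [0, 1]. Residuals are exactly uncorrelated with
every numeric confound and invariant to affine confound rescaling — both
asserted in the test suite at 1e−10. Matrix inputs asymmetric by more
than 1e−8 are rejected; smaller asymmetries are symmetrized by averaging.

Missing values are rejected rather than imputed, and networks are kept
weighted (no thresholding or binarization).

## Stage identification

The τ column vectors are clustered by k-means (squared Euclidean,
randomized k-means++ seeding, one Lloyd run per repetition, no temporal
constraint) 100 times per candidate stage count G. The consensus matrix
C records co-clustering frequencies; its dispersion coefficient

ρ(C) = (1/τ²) Σᵢⱼ 4(Cᵢⱼ − ½)²

is 1 exactly when all runs agree. Among candidates attaining the maximal
ρ, the largest G is selected (finest granularity), and the final labels
come from the best-inertia run at that G, renumbered chronologically.
Seeding choice matters: uniform-random centroid seeding on well-separated
clusters frequently strands two centroids in one cluster — a stable Lloyd
local optimum — which caps consensus below 1 no matter how clean the
data; randomized careful (D²-weighted) seeding avoids this, which is why
it is the implemented reading of "randomized k-means". Stage contiguity
is not enforced; a non-contiguous selection is logged as a warning.

## Factorization

Stage blocks are approximated as Xᵗ ≈ Uᵗ Vᵗᵀ with non-negative factors,
near-orthonormal component columns in each Uᵗ, a shared trajectory
matrix V (stage rows selected by binary masks Hᵗ), a ridge ½λ‖V‖² (the
nuclear-norm surrogate of the per-stage product under the orthogonality
constraint), and chain-graph smoothness penalties: (α/4) ΣW_U(k,l)‖Uᵏ −
Uˡ‖² over chronologically consecutive stages and (β/4) ΣW_V(i,j)‖vᵢ −
vⱼ‖² over consecutive time points. Chain topology is chosen because the
penalties encode *temporal* smoothness; any weighted adjacency can be
substituted.

### Updates and their damping

V follows the standard graph-regularized multiplicative rule

V ← V ⊙ [Σₜ Hᵗ Xᵗᵀ Uᵗ + β W_V V] / [Σₜ Hᵗ Hᵗᵀ V Uᵗᵀ Uᵗ + λV + β D_V V].

U is updated stage-by-stage (Gauss–Seidel over stages, each using its
neighbours' latest states) with the Lagrangian orthogonal form, numerator
Xᵗ Vᵗ + α Σ W_U(t,k) Uᵏ and denominator Uᵗ(Vᵗᵀ Xᵗᵀ Uᵗ) + α Σ W_U(t,k)
Uᵗ Uᵗᵀ Uᵏ. Two numerical points matter:

1. **Damping.** The raw ratio is a fixed-point map that overshoots: in
   alternation with the V update it produces a period-2 oscillation of
   the objective (observed jumping by an order of magnitude on planted
   data). The implemented update applies the multiplier to the power ½ —
   the standard damping for Lagrangian-constrained multiplicative rules —
   which has exactly the same fixed points (an exact factorization with
   orthonormal Uᵗ gives multiplier 1) and descends in practice.
2. **Safeguard.** Far from the orthogonality manifold (e.g., at a dense
   random initialization with p ≥ 4) even the damped sweep can
   occasionally increase the objective. Each U sweep is therefore
   accepted only if the objective does not increase; otherwise it is
   retried at exponents ¼ and ⅛, and as a last resort the previous state
   is kept for that sweep. This makes the objective trace non-increasing
   by construction while leaving the update rule untouched wherever it
   already descends (the safeguard activates only in the first few
   iterations of adversarial starts). A small ε = 1e−12 guards every
   denominator; multiplicative zeros stay zero.

Initialization draws every factor uniform on (0, 1], normalizes Uᵗ
columns to unit length, and rescales V by the global least-squares
constant matching ‖X‖, so restarts begin at comparable objective values.
By default 100 restarts are run (mirroring k-means practice) and the one
with the least final objective is kept; convergence is declared when the
relative objective change drops below 1e−6 or after 1000 iterations.
Experiments in this repository use fewer restarts (3–6) and more
iterations (1200–3000) — for this problem class restarts mostly agree
and the binding resource is per-restart convergence depth.

λ = α = β = 0.1 by default: the method is robust over a wide range of
regularization strengths, and these sit mid-range; all three are exposed
in `DMDConfig`.

### Orthogonality is encouraged, not enforced

The Lagrangian multiplicative scheme drives Uᵗᵀ Uᵗ toward I but its
stationary points satisfy the constraint only approximately: converged
noiseless planted runs sit at ‖UᵗᵀUᵗ − I‖_F ≈ 0.22–0.30 (dominated by
column norms equilibrating slightly below 1; off-diagonals ≈ 0.05).
Variants that symmetrize the multiplier matrix or transpose the inner
product reduce the gap to ≈ 0.18–0.20 but lose strict monotonicity, so
the package keeps the monotone form and reports the gap per stage as a
diagnostic (`DMDResult.orthogonality_gap`) instead of rescaling factors
post hoc. Recovery quality is unaffected: on planted models at 5% noise
the Hungarian-matched cosines of components and trajectories both exceed
0.95 on average.

### Choosing the number of components

The Minimal Trajectory Distance is the smallest pairwise Euclidean
distance among L2-normalized trajectory columns; normalization makes the
criterion comparable across p, and ties select the smaller p (parsimony).
`select_num_dms` fits every candidate and returns the argmax. A caveat
established empirically in this repository: on synthetic data whose
planted components occupy *disjoint* edge supports, the MTD curve does
not rise to a peak at the planted p — low-p fits keep components
essentially pure rather than blending trajectories, so their minimal
trajectory distance matches the planted separation and the argmax lands
at the smallest candidate. An interior MTD peak requires the components
to share a dominant global pattern (as real structural correlation
networks do), which the disjoint-support generator deliberately excludes.
The selection *machinery* (argmax rule, tie-breaking, MTD arithmetic) is
fully tested; the peak-at-truth behavior should not be expected on
parts-based synthetic data.

## Characterization

For component r with stage states collected in U_r (M × G):

- **Normalized divergence** Ω_m = Σ_{k,l} |U_r(m,k) − U_r(m,l)| / mean_t
  U_r(m,t), summed over ordered stage pairs (the factor 2 does not affect
  ranking); zero-mean edges get Ω = ∞ and can never rank as stable.
- **Strength threshold** δ_r = RMS of all G·M entries of U_r; edges with
  mean strength below δ_r are excluded before the top fraction (2% of M
  by default) of least-divergent survivors is selected, ties resolved
  toward the stronger edge. Exclusion-before-fraction is the implemented
  order (configurable).
- **Rapid changes**: per adjacent-stage transition, Δu per edge and the
  stage-contribution change Δv̄ (difference of within-stage trajectory
  means); a rising contribution reports the top-fraction most-increased
  edges (Δu > 0), a falling one the most-decreased, an exactly-zero Δv̄
  reports nothing rather than guessing a sign.

## Reproducibility

Odd-positioned and even-positioned time points form two halves (for ages
3–20: 3, 5, …, 19 vs 4, 6, …, 20), each inheriting the full-sequence
stage labels restricted to its time points (re-estimation available
behind a flag; inheritance isolates factorization variance from
clustering variance). A stage emptied in one half is merged with its
chronological neighbour, with a warning. Components are matched across
halves by the Hungarian algorithm on cosine similarity of their
concatenated stage states (a component is its whole evolution);
trajectory columns are compared under the same permutation. Cosine
similarity judges orientation, not magnitude — appropriate since the
halves are offset by one time step.

## Synthetic data

`generate_planted_networks` emits X = U*^{stage(i)} V*(i,·)ᵀ + noise with
p components on disjoint edge supports (hence exactly orthonormal states;
default support ≈ 5% of M edges each, entries uniform in [0.5, 1.5] then
column-normalized), a per-transition support turnover of `drift` (default
0.1: 10% of each support swaps for fresh edges, new entries drawn fresh,
column renormalized), and noise that is Gaussian truncated at zero
(negative draws clipped; half-normal available by flag) with default sd
0.02 ≈ 5–8% of the mean nonzero signal entry. Defaults N = 40, τ = 12,
G = 3 equal contiguous blocks, p = 3.

Two trajectory families are provided. The default `classic` family uses
gentle positive curves (decaying, rising, unimodal, flat, u-shaped,
late-rising) of the kind seen in developing structural networks; their
shared positive offset keeps within-stage column variation small, so the
planted stage structure dominates the k-means geometry (between-stage
column gaps ≈ 4–5× the within-stage scatter at defaults, which is what
makes the consensus dispersion hit 1.0). The `separated` family places
the p trajectory deviations (amplitude 0.8 around baseline 1.2, built
from smooth cosine modes) at the vertices of a regular simplex — the
maximally and equally separated configuration — for component-number
experiments.

What the generator does *not* emulate: realistic network topology
(small-worldness, hubs, distance-dependent weights), subject-level
sampling variability in the correlations, shared global components
across meta-networks, and longitudinal within-subject dependence.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated generative model, not performance
on real cortical data.

`generate_thickness_tables` emits per-age subject × ROI tables from a
latent-factor model (ROIs round-robin-assigned to factors; loading 0.8,
residual sd 0.3 around a 2.5 mm baseline) plus the two confounds the
regression stage is expected to remove: a gender offset (0.1 mm) and a
per-subject whole-cortex factor (sd 0.15 mm). Default 45 subjects per
age, 18 ages starting at 3.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run at N = 40 (M = 780) with τ = 12–18,
100 consensus runs, 2–6 restarts and 1200–3000 iterations per fit, and
10–20 seeds per stochastic claim; the thickness-table checks use N = 78
with 45 subjects per age. These sizes make every experiment exact enough
to assert while keeping the whole suite in the minutes range on one CPU.

## Known limitations

- Orthogonality is approximate at stationarity (gap ≈ 0.2–0.3; see
  above); downstream characterization uses only ratios and rankings that
  are invariant to the residual scale imbalance.
- The multiplicative scheme converges slowly near the optimum
  (sublinear tail); deep convergence needs thousands of iterations,
  which is why experiment configs raise `max_iter` beyond the default.
- MTD-based selection assumes components share enough global structure
  for underfitted trajectories to blend; see the caveat above.
- Stages are cross-sectional constructs; within-subject longitudinal
  dependence is out of scope.
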