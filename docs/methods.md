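# Methods

This note records the modeling choices behind `tsgeo`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical details a maintainer would need to change any of it.

## Problem setting and assumptions

The package treats TS-structure prediction as regression on interatomic
distances. Its assumptions:

* **Atom mapping is positional.** Atom `i` of the reactant is atom `i` of
  the product (and of the reference TS, when present). No mapping inference
  is attempted; inputs that are not mapped must be mapped upstream.
* **Endpoints are consistently posed.** Linear interpolation between
  arbitrary poses of reactant and product produces collapsed geometries, so
  an optional Kabsch pre-alignment of the product onto the reactant
  (`align_before_interp`, proper rotations only) is available; it is off by
  default because generated and curated datasets are already consistently
  posed.
* **Distances suffice.** All featurization is based on atomic numbers and
  interatomic distances, which buys exact rigid-motion invariance and costs
  the ability to distinguish enantiomers. Chirality of reconstructed
  geometries is therefore uncontrolled; this is a known limitation, not a
  bug.

## Featurization

Each pair feature concatenates two learned atomic-number embeddings with a
Gaussian-grid expansion of the pair distance, `exp(−γ (d − μ_k)²)`.
Defaults: 64 grid points on [0, 8] Å (covering every chemically relevant
distance in small organics), `γ = 1/(2·spacing²)` so adjacent kernels
overlap at ~0.6, and 32-wide embeddings, giving the initial feature width
2·32 + 64 = 128. The embedding table covers H, C, N, O by default and is
extensible via `FeaturizerConfig.elements`; it is trained end-to-end from a
random normal initialization.

Pairs are stored once per unordered pair, diagonal included
(`N(N+1)/2` rows). Within a row the two embedding slots are ordered by
element (larger Z first) rather than by atom index: atom indices carry no
chemical meaning, and an index-based order would break the requirement
that consistently renumbering the atoms only permutes the outputs.
Diagonal pairs (d = 0) are featurized but masked out of every loss and
readout — their ratio target would be 0/0.

## Architecture

Each PSI layer applies (1) one pre-norm transformer encoder block (4 heads,
feed-forward width 2× the feature width, shared across the three structure
slices) over the pair axis of each structure, then (2) a bidirectional GRU
over the three-structure sequence per pair, whose hidden width equals the
input width so the forward/backward concatenation exactly doubles the
feature size. Two stacked layers take the width 128 → 256 → 512. The
encoder internals are the smallest standard configuration consistent with
"a transformer encoder"; layers do not share weights.

The ratio head is a two-layer perceptron (hidden 256) applied per strict
pair to the interpolated-structure slice of the final features; its output
layer is zero-initialized and exponentiated, so an untrained model predicts
ratio 1 everywhere — i.e. exactly the interpolated geometry — and ratios
are positive for any finite weights. The optional property head (off by
default) maps atom-aggregated reactant/product features (`f_i = Σ_j f_ij`,
symmetric recovery of the unstored triangle) to per-atom contributions to
E, S_vib, S_rot; molecular values are their sums. The head covers reactant
and product only, matching the roles for which the auxiliary loss is
defined; a TS-role output would have no label in either supported dataset
layout.

Batching concatenates reactions along the pair axis: projections and
recurrences are shared matmuls, while attention and the readouts respect
per-reaction block boundaries, so batched outputs are bitwise-equal to
single-reaction processing (this is asserted in the tests).

## Losses

* `L1`: molecular MAE of predicted TS distances, averaged per reaction and
  then over the batch (molecule-first averaging, matching the metric).
  Computed in Å internally; metrics are reported in pm (100 pm/Å).
* `L2`: sum over roles (reactant, product) and labeled targets
  (E, S_vib, S_rot) of the MAE between summed atomic contributions and the
  label; unlabeled targets are skipped silently.
* `L3`: with eigenvalues `e_1..e_N` of the squared-distance matrix sorted
  by descending magnitude and `m = min(5, N)`,
  `L3 = Σ_{i≤m} e_i + Σ_{i>m} |e_i|` (each eigenvalue counted once).
  Algebraically `L3 = 2·Σ_{i>m} max(0, −e_i)`: it vanishes for every
  distance set realizable in 3-D and penalizes non-embeddable sets whose
  residual spectrum dips negative. For `N ≤ 5` it reduces to the trace of a
  hollow matrix and is identically zero — the penalty only constrains
  systems with more than five atoms. Eigenvalue gradients use
  `∂e_k/∂A = u_k u_kᵀ`, valid away from degeneracies; training batches are
  generic so this is not a practical concern.
* Total: `L = c·L1 + c′·(L2 + L3)`, defaults `c = 2000`, `c′ = 0`. With
  `c′ = 0` the auxiliary terms are skipped entirely (not just weighted to
  zero). The hyperparameter grid used to diversify ensembles is
  `c ∈ {1, 2000} × c′ ∈ {0, 1, 10}`, configurable.

## Training and checkpoints

Adam (lr 1e-4 default, cosine decay to zero, batch 16 reactions,
300 epochs) on an 80-10-10 random by-reaction split; all randomness —
split, initialization, batch order — derives from one integer seed, and
identical seeds reproduce identical training curves exactly. After each
epoch the model state is a checkpoint candidate; the five states with the
best validation molecular MAPE are kept (the standard ensemble recipe is
6 hyperparameter combinations × 3 seeds × top-5 epochs = 90 members).

The scaled-down runs used by the test suite and the acceptance script train
a single default-architecture model on 200 generated reactions of 4–6 atoms
for 12 epochs at lr 1e-3 — sizes chosen so the full pipeline (data,
training, evaluation) demonstrates a clear learning signal over the
interpolation baseline in a few minutes on one core. The quality ceiling of
such a run is nowhere near what large-scale training achieves; the tests
assert the *signal*, not a benchmark number.

## Inference

TTA averages the distances predicted for the forward and reversed reaction
with a symmetric accumulation, so the result is bitwise invariant under
reversal. Averaging acts on distances as specified; with midpoint
interpolation the interpolated distances are themselves
reversal-invariant, so ratio- and distance-averaging coincide. Ensembles
evaluate members independently (order-independent by construction), keep
every member's distance set for the joint reconstruction, and expose the
per-pair mean for metrics. When TTA and ensembling are combined, distances
are averaged first and one joint optimization follows.

## Reconstruction

The weighted L1 objective is non-smooth; `|x|` is replaced by
`sqrt(x² + ε²)` and minimized with L-BFGS-B (memory 20) in a graduated
schedule ε = 1e-4 → 1e-6 → 1e-9 Å from the interpolated start. The warm
first stage keeps the surface benign far from the optimum; the polish
stages sharpen the kink so exact-distance problems converge to ~1e-10 Å.
Termination is effectively by stationarity (ftol 1e-15, gtol 1e-14,
max 5000 iterations per stage); non-convergence returns the best-found
geometry with a flag rather than raising. Weights use the ensemble-mean
predicted distance, `w_ij = exp(−α d̄_ij²)`, α = 0.2 Å⁻² — short
(bonded-range) distances dominate the fit. The reported objective is the
exact (non-smoothed) weighted L1 value at the solution.

## Normal-mode exploration

Sampling displaces the equilibrium along each real mode by
`q = ±sqrt(2 c kT / k_mode)` with `c ~ U[0,1]` (mass-weighted coordinates),
giving an expected harmonic energy of kT/2 per mode; T = 0 reproduces the
equilibrium exactly and imaginary-frequency modes are excluded. Sampled
product conformers are Kabsch-aligned onto their sampled reactants before
prediction. Candidate TSs are clustered by affinity propagation
(scikit-learn) on flattened strict-pair distance vectors — negative squared
Euclidean similarity, damping 0.9, median-similarity preference; exemplars
are members of the input set, and a non-convergent message-passing run
falls back to the global medoid with a warning. Default sampling depth is
2000 pairs at 300 K; the number of representatives is data-dependent.

## Synthetic data

The generator emulates atom-mapped single-step reactions with an exactly
realizable reference TS:

* reactants grow as random chains with bond lengths near element-dependent
  equilibrium values and a 0.8 Å minimum separation;
* products either transfer one atom between neighbors (creating one bond
  breakage and one formation — a minority of all pairs, mimicking how rare
  changing pairs are in reaction databases) or deform smoothly (radial
  stretch), plus small Gaussian jitter;
* the reference TS is the coordinate midpoint plus a bend of magnitude
  `bend_scale·‖Δ‖` per atom, directed along the component of the atom's
  radial vector orthogonal to its displacement Δ. This direction is a
  deterministic, rotation- and reflection-equivariant function of the
  endpoints, so the TS distance set is fully determined by the
  reactant/product distance matrices — i.e. the ratio targets are learnable
  from what the model sees, as for real reactions. Built in coordinate
  space, the targets automatically satisfy the Euclidean constraint
  (L3 = 0) and stay within ratio bounds [0.5, 2] (enforced by retry);
* property labels come from a smooth Morse-like pairwise toy energy with
  element-dependent depths and radii, plus entropy-like functionals of the
  distance set. They are deterministic and smooth but chemically
  meaningless — they exercise the multi-label plumbing, nothing more. The
  same potential provides analytic gradients (relaxation) and an analytic
  Hessian whose mass-weighted modes drive the exploration tests.

What passing tests on this data shows: the architecture can extract a
geometric signal that linear interpolation misses, and every pipeline stage
composes correctly under its exact invariances. What it does not show:
accuracy on real quantum-chemical reaction data, transferability across
reaction families, or the quality of the toy labels.

## Known limitations

* Chirality of reconstructed TSs is uncontrolled (inherent to distances).
* The EDM penalty is inert for systems of ≤ 5 atoms and blind to
  non-embeddable sets whose residual spectrum is positive.
* The property head and auxiliary losses default to off (`c′ = 0`); they
  are implemented and tested but not exercised by the default training
  path.
* No GPU path: the NumPy engine is adequate for the scaled problem sizes
  the package targets, not for database-scale training.
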