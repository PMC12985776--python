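# Methods

This note records the models, numerical choices and study conditions the
package implements, in the order data flows through the pipeline.

## Synthetic vascular phantoms

A phantom starts as a planar vessel graph: a six-segment trunk crossing
the field of view, one to five side branches fanning upward with
monotonically varying angles (so neighbouring limbs never collide), and
collateral loops added as arcs below the trunk. Each loop is an explicit
arc joining two existing nodes through fresh midpoints, so adding it
raises β₁ by exactly one; the Euler formula β₁ = E − V + C therefore
equals the generator's loop count by construction, which the test suite
verifies over hundreds of seeds. Geometry jitter is kept small enough
that the rasterized tubes (flat core, 1-pixel Gaussian feathered rim,
radii 1.5–2.5 px at the 128² reference grid) can neither merge nor open
spurious holes; pixel-scale gaps in junction wedges that survive
discretization are filled (holes ≤ 8 px), since they are artifacts of the
capsule union, not anatomy.

MR intensity is 1 inside vessels over a 0.1 background; PET activity is
1.0 inside vessels over 0.1 background, scaled at simulation time to a
total-count budget. Phantoms are 2-D (64–256² grids; radii below 1 px
raise a sizing error, which excludes 64² at default radii). All
randomness passes through one integer seed per call.

## MR model

k-space is DC-centered; the encoding operator is the orthonormal centered
2-D FFT, so the adjoint is the exact inverse. Complex Gaussian noise of
total variance σ² per sample (default σ = 0.02) is added on acquired
locations only. Two mask families exist:

* **pointwise variable-density Poisson-disc** (static-CS baseline in its
  3-D-acquisition idealization): local minimum distance
  r₀·(1 + 4ρ^q) with radial exponent q = 2, r₀ calibrated by bisection to
  the target fraction (±few % relative);
* **line masks** — whole phase-encode rows, the unit the closed-loop
  controller (and 2-D Cartesian hardware) actually acquires; the static
  line baseline spaces rows by a 1-D variable-density Poisson-disc with a
  fully sampled 8% center block.

Partial Fourier (default fraction 0.625) restricts acquisition to rows
below the extent; unacquired conjugate-symmetric locations are filled
with the conjugate of their mirrored twin, valid because the phantoms are
real-valued. No phase correction is performed; instead the solver
estimates a single global phase from the DC sample and factors it out,
which makes |u| exactly invariant to a global phase on the data.

## PET model

2-D parallel-beam geometry with 60 evenly spaced angles in [0°, 180°).
The projector is pixel-driven with linear detector splatting: each pixel
deposits its activity into the two bins bracketing its projected
position. This makes every angle's projection carry exactly the total
image mass, keeps the backprojector the exact matrix transpose (both are
one cached sparse matrix), and sizes the detector to the grid diagonal so
no pixel is ever clipped. Counts are Poisson around the expected
sinogram plus a spatially uniform randoms/scatter rate r (default
0.2/bin); the default total-count budget is 2×10⁵ over the full 60-angle
acquisition — a deliberately low-count, clinically flavoured regime in
which priors matter. OS-EM uses interleaved angle subsets (desk default
3 iterations × 4 subsets as a scaled-down version of clinical 3 × 21;
the joint solver runs its own EM sweeps); zero-sensitivity pixels are
excluded from the update.

## Joint reconstruction

The objective combines the MR data term, the PET negative Poisson
log-likelihood, TV priors on both images, and the edge-weighted TV
coupling C(u,x) = Σ exp(−|∇u|/η)|∇x| with η set to the median nonzero MR
gradient of the current iterate. The coupling acts on the PET side only
(MR is the structural scaffold). Per outer iteration (default 8–10):

1. **u-step** — unit gradient step on the conjugate-filled data term
   (the composite operator has unit norm), optional structured-Hankel
   projection of k-space rows (window 16, SVD truncation, anti-diagonal
   re-averaging; disabled by default), then the TV proximal map.
2. **x-step** — one EM sweep over subsets, then the proximal map of the
   combined PET prior: a spatially weighted TV with per-pixel strength
   (λ₂ + λ₃·exp(−|∇u|/η))·s·x₉₅, where x₉₅ is the 95th activity
   percentile (activity carries the count scale) and s = 0.02 converts
   the dimensionless λ's into a prox step. The weighted-TV prox is
   solved by Chambolle dual ascent (τ = 1/8, 30–40 iterations) with the
   per-pixel dual constraint |p|ᵢ ≤ aᵢ. This EM-then-prox scheme
   replaced a one-step-late penalized-EM variant, which is unstable when
   the penalty gradient turns negative.

Defaults λ₁ = 0.08, λ₂ = 0.05, λ₃ = 0.5 come from a coarse grid search on
held-out seeded phantoms at 30% sampling; with them the coupling strictly
improves PET error over λ₃ = 0 because the edge-aware term supplies most
of the smoothing while sparing MR-coincident edges. The objective trace
is monitored each outer iteration; alternation admits ≤1% transient
increases, and a relative change above 10⁻³ at the last iteration sets a
non-convergence flag rather than raising.

## Topology

Persistent homology uses superlevel sets of intensity on the pixel grid
(vessels are bright): degree 0 by union-find over pixels in decreasing
intensity (8-connected), degree 1 by Alexander duality as components of
the growing 4-connected complement on a padded grid. Diagrams are stored
sign-flipped so death ≥ birth; one essential class per component dies at
the global minimum. The ground metric on the plane is L∞ (diagonal cost
= persistence/2); Wasserstein order defaults to p = 2 for uncertainty,
with p = 1 supported.

The exact distance solves linear assignment on the diagonal-augmented
cost matrix. The sliced approximation projects both diagonally-augmented
point sets onto n directions (default 50, seeded), takes the union of the
rank-matchings as a sparse candidate graph, and solves a minimum-weight
perfect matching restricted to it; each direction alone yields a feasible
matching, so the estimate upper-bounds the exact distance and converges
to it with more projections (~1% mean relative error on random diagrams
of 10–100 points). A classic averaged-1-D-cost estimator was evaluated
first and rejected: it measures a different functional and sits ~35% off
the exact distance on the same ensemble.

Vascular graphs come from Otsu thresholding (holes ≤ 8 px filled),
skeletonization, and condensation of the skeleton pixel graph to
junction/endpoint vertices; diagonal pixel links are added only where no
orthogonal path exists and filled unit squares are broken, so graph
cycles correspond to actual holes. β₀ is the component count, β₁ = E − V
+ β₀.

## Closed-loop controller

State descriptor: (β₀, β₁, total persistence per degree, U_t, budget
fraction used, fraction of lines, fraction of angles), with feature
counts taken after pruning diagram points below 0.05 persistence (the
noise floor at σ = 0.02). Actions are bundles of 8 unacquired lines or
blocks of 5 angles; the warm start acquires the central 8% of k-space
lines and 10 coarse uniform angles. MR and PET actions interleave
freely.

**Reference diagram.** The uncertainty and the stopping rule are
referenced to the *converged* (fully sampled) reconstruction's diagram.
The phantom-truth oracle reference is available as an option, but
reconstruction bias (TV shrinkage of the dominant features) puts a
systematic ~7–9% floor on the oracle-referenced deviation at any sampling
fraction, so an absolute few-percent criterion is only meaningful against
the converged reference — which is also what a fully sampled reference
scan provides in practice. In deployment mode (no reference available) a
self-referenced variant compares consecutive steps.

**Why MR carries the topology signal.** The vascular graph is read from
the MR (angiographic) channel. At desk-scale count levels PET diagrams
are noise-dominated (normalized deviations of 45–120% against any
reference, non-monotone in angle count), so PET acquisition cannot be
driven by an absolute topological threshold. Instead, after each angle
block the newly measured projections are compared with their forward
prediction from the pre-block estimate; when the Poisson-standardized
misfit χ² drops to ≤ 1.5 the block carried no information beyond noise
and PET acquisition stops. With the MR-coupled reconstruction this
typically happens after a single block beyond the warm start — the
simple-phantom regime genuinely needs few angles.

The greedy controller evaluates MR candidates by a cheap provisional
reconstruction (conjugate-filled zero-filled inverse FFT) and exact
Wasserstein distances on pruned diagrams; the stopping rule is the
normalized persistence deviation ≤ 3% for two consecutive steps plus PET
consistency, or budget exhaustion. Sampling fractions count acquired
units over all 128 lines + 60 angles.

The actor–critic alternative scores each candidate through a two-layer
perceptron on the concatenated (normalized) state descriptor and action
features, with a separate critic trained by TD(0). State inputs are
scaled to O(1) before the shared layer — without this the Betti counts
numerically swamp the action features and the policy cannot condition on
actions. Training runs on a fast surrogate environment (96² phantoms,
cheap MR reconstruction only) with a small smoothness weight so the
topological and time terms dominate the learning signal; the greedy
controller is used for all quantitative evaluation, the policy is
validated by its property tests (bandit convergence, critic fixed point,
improvement over the untrained policy).

## Tier-I evaluation

Each realization draws a seeded phantom with 1–3 collateral loops,
reconstructs a fully sampled reference (independent noise), runs the
accelerated acquisition, and records retained sampling %, Δβ₀, Δβ₁
(graph-based, percent deviation from the reference reconstruction), and
the normalized Wasserstein-weighted persistence deviation
100·U(D_acc, D_ref)/U(D_ref, ∅) with w₀ = w₁ = 0.5, p = 2. The default
experiment uses 50 realizations (a desk-scale stand-in for
thousand-realization studies; summary SDs are correspondingly wider) at
128², chosen to keep the full study within minutes on one CPU. The
static baseline matches the closed loop's per-realization sampling
fraction with a variable-density Poisson-disc over *lines* — the same
physical acquisition unit; the pointwise 2-D mask variant remains
available but idealizes a 3-D acquisition and is strictly more incoherent
than any line-constrained scheme. Reported percentages round half-even
to one decimal.

## What the generator does and does not emulate

The phantoms capture the features the method is about — bright connected
vasculature with loop structure on a quiet background, partial-volume
feathering, measurement noise in both modalities — but not anatomical
realism: no 3-D geometry, no flow or motion, no coil sensitivities, no
attenuation or scatter physics, no intensity texture. Passing tests
therefore demonstrate that the closed-loop machinery preserves known
topology under undersampling in a controlled setting; they do not
establish in-vivo performance.

## Known limitations

* One-way coupling: PET never feeds back into the MR image, so PET data
  cannot reduce MR-topology uncertainty by construction.
* The greedy look-ahead peeks at simulated measurements for candidate
  scoring (standard phantom-study idealization of "expected" reduction).
* Degree-2 homology (3-D voids), non-Cartesian trajectories, and
  multi-coil encoding are out of scope.
* The sliced-Wasserstein estimator is an upper bound; it is not a metric
  in its own right (the classic sliced construction is, but is far from
  the exact distance in value).
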