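# inie — topology-aware closed-loop MR–PET acquisition simulation

`inie` is a desk-scale simulator and library for *closed-loop,
topology-aware compressed-sensing* hybrid MR–PET imaging of the cerebral
vasculature. In acute stroke imaging, what matters clinically is not
pixel-wise fidelity but the **topology of the vascular graph** — how many
connected components (β₀) and collateral loops (β₁) the reconstruction
preserves. `inie` turns that observation into an acquisition controller:
the scanner model acquires k-space phase-encode lines and PET projection
angles *adaptively*, steering each new measurement toward the largest
expected reduction in topological uncertainty, and stops as soon as the
vascular topology has converged.

The package is aimed at researchers in computational imaging and applied
topology who want a fully synthetic, reproducible test bed: every
experiment runs on seeded 2-D vascular phantoms with analytically known
Betti numbers, so topological claims can be checked against ground truth.

## The model

**Joint reconstruction.** Given undersampled complex k-space samples
`y_MR = Φ_MR F u + n` and Poisson sinogram counts
`y_PET ~ Poisson(Φ_PET x + r)`, the MR image `u` and PET activity `x ≥ 0`
solve

```
min_{u,x}  ‖Φ_MR F u − y_MR‖₂² + λ₁ R_MR(u)
         + 1ᵀ(Φ_PET x + r) − y_PETᵀ log(Φ_PET x + r)
         + λ₂ R_PET(x) + λ₃ C(u, x)
```

with isotropic total-variation priors `R_MR`, `R_PET` and an edge-weighted
TV coupling `C(u,x) = Σᵢ exp(−|∇u|ᵢ/η)·|∇x|ᵢ` that transfers MR edge
structure into the PET reconstruction. The solver alternates proximal
gradient on `u` (with partial-Fourier conjugate filling and an optional
structured Hankel low-rank k-space projection) with ordered-subsets EM on
`x` followed by the proximal map of the weighted-TV prior.

**Topological uncertainty.** Persistence diagrams `D_t` of the superlevel
intensity filtration summarize the evolving anatomy. The controller's
uncertainty is

```
U_t = Σ_{k∈{0,1}} w_k · W_p(D_t^(k), D*^(k))
```

the weighted Wasserstein distance to a reference (converged) diagram,
per homology degree. A sliced approximation (candidate matchings induced
by 1-D projections) tracks the exact optimal-transport distance to within
about 1% while scaling subquadratically.

**Control.** A greedy one-step look-ahead scores every candidate line
bundle / angle block by a cheap provisional reconstruction and picks the
argmin of expected `U_t`; an actor–critic policy trained by
temporal-difference learning on the reward
`R_t = −α·U_t − β·T_t − γ‖x_t − x_{t−1}‖₂²` provides the learned
alternative. The loop stops when the normalized persistence deviation
stays below 3% for two consecutive steps and newly measured PET angles are
statistically consistent with the current estimate.

## Worked example

Run one closed-loop episode on a seeded two-loop phantom:

```bash
inie run --phantom-seed 3 --n-loops 2 --out run3
```

prints (abridged):

```json
{
  "sampling_fraction_pct": 30.32,
  "sampling_reduction_pct": 69.68,
  "persistence_deviation_pct": 1.51,
  "beta_ref": [1, 2],
  "beta_acc": [1, 2],
  "n_lines": 42,
  "n_angles": 15,
  "n_steps": 6
}
```

Reading: the controller stopped after acquiring 42 of 128 k-space lines
and 15 of 60 PET angles — 30.3% of all measurable units, i.e. a **69.7%
sampling reduction** — while the normalized Wasserstein-weighted
persistence deviation against the fully sampled reference reconstruction
was **1.5%**, and both Betti numbers of the vascular graph (one component,
two collateral loops) were preserved exactly. The per-step trace
(`run3/trace.csv`) shows `U_t` collapsing from 0.49 to 0.02 within the
first three line bundles.

Other entry points:

```bash
inie benchmark-wasserstein            # sliced vs exact Wasserstein error
inie reproduce-tier1 --n 50 --seed 7  # full topology-preservation study
inie train-policy --n-episodes 100    # actor-critic training
```

or from Python:

```python
from inie import generate_vessel_tree, rasterize_phantom, run_closed_loop

phantom = rasterize_phantom(generate_vessel_tree(seed=3, n_loops=2), 128)
trace = run_closed_loop(phantom, mode="greedy", seed=3)
print(trace.final_metrics)
```

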