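# Methods

This note records the model, the numerical choices, and the limitations of
the `tractsurf` pipeline in enough detail to reimplement it.

## Overview

The pipeline asks whether the *shape* of white-matter tract boundaries
carries group information beyond traditional region-of-interest (ROI)
measures (tract volume, mean fractional anisotropy).  Per subject and
tract it produces two scalar fields on the vertices of an atlas surface:

* **surface deformation map** — the log-Jacobian determinant of the
  atlas-to-subject diffeomorphism at every atlas vertex (negative values =
  local tissue compression relative to the atlas);
* **projected FA map** — the subject's FA sampled onto the matched
  surface by nearest-vertex pooling of tract voxels.

A statistical battery (vertex-wise GLM + permutation omnibus, PCA + LDA
classification, canonical scores vs. MMSE) then compares groups on these
maps and on the ROI baselines.

## Surface matching (currents-based LDDMM)

A tract surface is represented as a *current*: each triangle contributes a
Dirac at its centroid weighted by its area-scaled normal (half the edge
cross product).  The mismatch between surfaces `S` (deformed atlas) and
`T` (subject) is

```
E(S,T) = <S,S> + <T,T> - 2<S,T>,
<S,T>  = sum_{f,g} k_W(c_f, c_g) N_f . N_g,   k_W(x,y) = exp(-|x-y|^2 / sigma_W^2)
```

which requires no point correspondence and is orientation-sensitive.

Deformations are kernel flows: control points `q_j` carry momenta
`alpha_j` (constant in time, riding with the points), and any point moves
by forward-Euler integration of

```
dx/dt = v_t(x) = sum_j k_V(x, q_j(t)) alpha_j
```

over `T = 10` steps on a unit time horizon.  The objective is
`path-norm + weight * E(phi(atlas), subject)` with the path norm
`int sum_ij k_V(q_i,q_j) alpha_i.alpha_j dt`.  The gradient in the initial
momenta is computed by an exact reverse-mode (adjoint) pass through the
discretized flow — it is the derivative of the discrete objective, not a
discretization of the continuous adjoint ODE — and was verified against
central finite differences (relative error ~1e-5).  Optimization is
gradient descent with backtracking line search (accepted-iterate trace is
monotone), growing the step 1.5x after each accepted step.

Defaults: `sigma_V = 10 mm` (deformation kernel, about the tract diameter,
so matched deformations are near-rigid at small scales and volume change
concentrates where the data demand it), `sigma_W = 5 mm` (matching kernel,
about half the tract diameter — fine enough to see the planted patch,
coarse enough to ignore mesh discretization), `weight = 1`, at most 100
control points (subsampled atlas vertices), 60 iterations at relative
tolerance 1e-5.

## Deformation and FA maps

The log-Jacobian is computed from the *3-D volume* Jacobian of the fitted
map by central finite differences with probe step `h = 0.25 mm` at each
atlas vertex (6 probes per vertex, batched).  A non-positive determinant
raises rather than returning NaN.  Note a subtle point validated in the
tests: a pure surface indentation need not change the volume Jacobian *at*
the surface; the planted effect therefore compresses a ball of tissue
centred inside the tract, which forces genuine volume loss at the
boundary.

FA projection assigns every labelled tract voxel (world-mm center) to its
nearest mesh vertex — exact distance ties go to the lowest vertex index —
and each vertex averages its assigned voxels.  The voxel-count-weighted
mean over assigned vertices therefore equals the tract mean FA exactly
(conservation identity, tested).  Vertices with no assigned voxel fall
back to their single nearest tract voxel and are excluded from the
identity.

## Volumetric segmentation (multi-channel greedy fluid registration)

Tract labels are carried from the atlas into each subject by registering
the FA and b0 channels jointly: a 12-parameter affine pre-alignment
(Powell, multi-resolution) followed by a greedy viscous-fluid scheme — the
sum-of-squared-differences force field is smoothed by the inverse fluid
operator `(gamma I - alpha Laplacian)^-1` in the Fourier domain, with a
cascade of elasticity ratios `alpha/gamma = 0.01, 0.005, 0.0025`
(coarse-to-fine stiffness), warm-starting each stage, a step guard that
rejects updates folding the grid (Jacobian <= 0), and cost-decrease
acceptance.  The result is a dense grid deformation (forward and inverse),
not a kernel flow.  Segmentation quality is scored by Dice overlap against
the generator's truth labels (0.74–1.0 at study scale); the group
analyses themselves consume the generator's subject surfaces, whose
vertices correspond one-to-one with the atlas by construction.

## DTI component

The diffusion scheme is 30 gradient directions at b = 700 s/mm^2 plus 5 at
b = 33 s/mm^2 (Fibonacci-sphere directions).  Tensors are fit by
log-linear least squares per voxel; FA comes from the eigenvalues as
`sqrt(3/2) ||lambda - mean|| / ||lambda||`.  The forward model and fit are
exact inverses in the noise-free case (machine precision, tested).

## Statistical battery

* **Vertex-wise GLM**: OLS per vertex, intercept + diagnosis (+
  intracranial volume for deformation maps; FA maps use diagnosis only);
  two-sided t test on the diagnosis coefficient.
* **Permutation omnibus**: the observed count of vertices with `p < 0.05`
  is compared with its distribution under random relabelling of diagnosis
  (covariates stay with their subjects); the overall p is the fraction of
  permutations reaching the observed count.  Implemented via the
  equivalent `|t| > t_crit` rule so the t survival function is evaluated
  once.  Type-I error is calibrated (7/200 null rejections at alpha=0.05,
  within the binomial interval; tested).
* **Classification**: PCA (centered SVD, at most n-1 components) ->
  pooled-t selection of components with `p < 0.05` -> LDA with
  leave-one-out cross validation.  Default "paper" mode computes PCA and
  selection on the full sample and cross-validates only the LDA fit;
  "nested" mode refits both inside every fold and is the leakage-free
  option.  Metrics use controls as the positive class (sensitivity = AD
  detection rate), rounded half-up to table precision.
* **Canonical scores**: leading eigenvector of `E^-1 H` (H the SSCP of the
  fitted group contrast, E the residual SSCP) over the selected
  components; the sign is fixed so AD scores the higher mean; scores are
  correlated with MMSE (Pearson, t-based p).
* **Multiple comparisons**: per-test Bonferroni threshold `alpha / n`.

## Synthetic cohort generator

Tracts are smooth implicit blobs (ellipsoid plus angular Gaussian bumps)
on a lattice inside a brain-like ellipsoid; labels are the positive set
and meshes come from marching cubes on the same field, so labels and
meshes are consistent by construction.  `mesh_step = 2` extracts surfaces
at half grid resolution (~220 faces per tract) — a speed/accuracy choice
exposed as a parameter.

Subjects are diffeomorphic warps of the atlas: a random kernel flow
(momenta ~ N(0, 0.6) at 30 control points, sigma = 10 mm) — i.e. *truth
within the model class of the matcher* — plus, for AD subjects, a
compression patch `x -> c + (x-c)(1 - A exp(-r^2/tau^2))` with
`tau = 6 mm` and amplitude `A = severity * 0.2` centred at the first
tract's centroid, where `severity ~ N(1, 0.2)` per subject.  Draws whose
grid Jacobian is not strictly positive are rejected and redrawn.  Volumes
are resampled through the inverse warp (backward-flow initialization plus
fixed-point refinement; inverse error ~1e-3 mm).  The FA reduction
(severity x 0.08 inside a 6 mm ball) is applied in the atlas frame before
warping.

Covariates: MMSE = group mean (28.8 control / 21.9 AD) + 4.0 x
(1 - severity) for AD + noise (SD 1.2 control / 2.5 AD — chosen so
controls sit near ceiling with little spread while AD spreads more, as
clinical MMSE does), clipped to [0, 30]; ICV ~ N(1.4e6, 1.2e5) mm^3,
independent of diagnosis.  All draws use `default_rng([seed, 1000 + i])`,
so any subject is reproducible in isolation.

What the generator does *not* emulate: imaging noise and bias fields,
partial-volume effects, topology changes, multi-site effects, or
correlated atrophy across tracts.  Problem sizes (48-voxel grid, 3 tracts,
19/13 subjects) are the package's own desk-scale defaults.

## Known limitations

* The currents mismatch fixes only the surface's *image*, not a
  parameterization: tangential sliding is unconstrained (a gauge freedom).
  Vertex-level log-Jacobian values within one tract are therefore stable
  for the strong radial patch effect but noisy for subtle tangential
  rearrangements; recovery of the *per-subject severity* from within-tract
  averages degrades when large random warps are superimposed, while
  group-level contrasts and the planted-patch localization remain robust
  (tested).
* The "paper" classification mode uses the full sample for PCA and
  component selection; its accuracies are optimistically biased.  Use
  `mode="nested"` for unbiased estimates.
* The permutation omnibus reports `p = 0` when no permutation reaches the
  observed count; the `(b+1)/(m+1)` estimator is available via
  `add_one=True`.
* Forward-Euler time discretization (10 steps) makes the fitted flow an
  approximate diffeomorphism; the integrator's inverse is accurate to
  O(dt) and refined to interpolation error where needed.
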