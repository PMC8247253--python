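# Methods

This note records the models, numerical choices and known limits of the
package, in the order the pipeline runs them.

## Phantom cohort

The generator's job is to emulate the statistical structure a free-water /
fiber-density lesion study assumes, not the anatomy of a brain. All
subjects share one grid (default 24 × 24 × 14 voxels at 1 mm³), standing in
for template registration, which is out of scope.

* **Geometry.** A WM slab fills the grid interior (two-voxel margin in x/y,
  the central z band); a one-voxel rim of purely hindered isotropic tissue
  ("GM") surrounds it, and the remaining background is free water ("CSF").
  The rim exists so three-tissue response functions can be estimated from
  the phantom itself. Lesions are 2–4 random ellipsoids (radii 1.5–3.5
  voxels) with centers biased toward the y = 0 face, which plays the role of
  the lateral ventricle. Lesions smaller than 8 voxels are redrawn so the
  quartile split is always defined; radii that cannot fit in the slab raise
  an error.
* **Ground-truth fields.** Inside lesions FW rises linearly toward the
  ventricle face, spanning `fw_lesion_range` (default 0.15–0.70);
  NAWM FW is 0.10 with a small smooth spatial perturbation. Fiber density is
  `density_base + coupling_beta · FW` (defaults 0.95 and −0.8), clipped at
  zero — the negative FW–density coupling is the mechanism under study.
* **Tissue model.** Fibers run along +x; a configurable fraction of WM
  voxels (default 0.3) carries a second population at 90°, which is what
  motivates spherical deconvolution over the single tensor. Damage
  (1 − density) moves the fiber tensor's diffusivities the way axonal
  degeneration and demyelination do: axial falls (slope 0.3 × 10⁻³ mm²/s per
  unit damage) and radial rises (slope 0.5 × 10⁻³). These slopes are of the
  size reported for severely damaged white matter; they were fixed once at
  design time. The voxel signal is the two-compartment mixture of free
  water (d = 3.0 × 10⁻³ mm²/s, the body-temperature value) and the fiber
  compartment(s), with s0 = 100 arbitrary units.
* **Noise.** Rician: magnitude of the signal plus two independent Gaussian
  channels of scale s0/SNR (default SNR 40, a typical 3 T value; the
  acquisition defaults — 30 directions, 1 b0, b = 1000 s/mm² — are generator
  parameters, not claims about any particular scanner).
* **Tabular data.** Age ~ N(49.7, 6.5) years, 71% female, disease duration
  log-normal (median 2 y), ICV ~ N(4200, 300) mm³ (a phantom-scale cranial
  volume so corrected lesion volumes land near 0.03–0.06). Hypertension is
  drawn from a logistic model on mean lesion FW, and outcomes (lacune,
  microbleed) from logistic models on mean lesion FW with hypertension as an
  extra term for microbleeds — making hypertension a true confounder of the
  FW–microbleed association, so the change-in-estimate procedure has
  something real to find. All randomness is keyed to one seed through
  per-subject child generators.

What the phantom does **not** contain: anatomy, susceptibility or motion
artifacts, EPI distortion, spatially varying coil bias, multi-shell
structure, or FLAIR/T1 contrast. Passing tests therefore demonstrate the
correctness of the numerics and the internal consistency of the method
chain, not performance on scanner data.

## Tensor and free-water fitting

The conventional tensor is fit by linear least squares on log signals; the
design includes an intercept for ln S0, and metrics come from eigenvalues
clipped at zero (AD = λ₁, RD = (λ₂+λ₃)/2, MD their mean, FA the usual
normalized dispersion). Voxels with non-positive signal are excluded and
logged.

Single-shell free-water fitting is the delicate stage: with one nonzero
shell, a bi-exponential and a slightly faster single exponential are nearly
indistinguishable, so the (fw, tissue) decomposition has a long, almost flat
valley — and is exactly degenerate for isotropic tissue. The estimator makes
three choices:

1. **Variable projection.** For any candidate fw the tissue tensor is the
   closed-form log-linear solution on the free-water-corrected attenuations
   (eigenvalues clipped to [0.1, 2.5] × 10⁻³ mm²/s), so the search is over a
   single scalar. A 45-point vectorized grid locates the basin; a bounded
   golden-section pass refines each voxel to 10⁻⁴. This solves the same
   box-constrained least-squares problem as a joint 7-parameter fit, but the
   inner step is exact and the outer problem is one-dimensional.
2. **Initialization prior.** fw₀ is read off the mean shell attenuation
   assuming a typical tissue diffusivity of 0.7 × 10⁻³ mm²/s. The objective
   adds `SSE_min · ((fw − fw₀)/0.1)²`, where SSE_min is the voxel's own
   residual floor from the grid. At zero noise the penalty vanishes and the
   fit is exact; in noise-dominated flat stretches the initialization
   decides. Measured on 500 independent anisotropic voxels: mean |error|
   0.034 at SNR 40, 1.6 × 10⁻⁴ noiseless.
3. **Spatial pass.** One normalized-Gaussian smoothing of the fw field
   inside the mask (σ = 1 voxel, weight 0.3, configurable, off for
   independent-voxel benchmarks), after which the tissue tensor is re-solved
   at the smoothed fw. This is an explicit, documented stand-in for the
   full spatially regularized functional of the original free-water
   elimination literature; no bit-equivalence with any published
   implementation is claimed.

Attenuations above 1.05 (or voxels with b0 ≤ 0) are clamped to 1 and
flagged; divergent voxels fall back to fw₀ and are flagged in the
diagnostics.

## Deconvolution and AFD

The WM response is the zonal spherical-harmonic profile of the top-300
highest-FA voxels (threshold 0.7) after rotating each principal direction to
the pole; GM/CSF responses are mean signals per shell; responses are averaged
across subjects before deconvolution, as group analyses require. The
per-voxel problem — WM FOD coefficients plus nonnegative GM/CSF fractions,
FOD nonnegative at 300 electrostatic constraint directions — is a convex QP.
With one b0 and one shell the three isotropic columns (WM l = 0, GM, CSF)
are linearly dependent; a 10⁻⁸-scaled ridge makes the QP strictly convex and
the inequality constraints pin the remaining flat direction. The QP is
solved exactly through its dual nonnegative-least-squares form
(Lawson–Hanson), so constraint violations sit at numerical noise
(~10⁻¹² of the peak amplitude) rather than at an iterative tolerance.
lmax defaults to 8 and lowers itself (with a logged warning) when the
acquisition has fewer measurements than unknowns — 31 volumes yield lmax 6.

Two behaviors of hard-constrained single-shell deconvolution are worth
knowing. First, the band-limited FOD of a sharp fiber has negative
sidelobes; forcing nonnegativity fills them with an l = 0 pedestal, so AFD
for a pure fiber sits a few percent above the response-defined unit and
isotropic tissue signal is partially absorbed by that pedestal instead of
the GM fraction. Second, normalization is a single global factor per subject
(median total tissue signal over WM set to 1) — a spatially varying bias
field is not simulated, so a bias-field model would be untestable dead code.
The phantom is generated at 1 mm³ directly, so no resampling stage exists;
real data at coarser resolution would need upsampling before this module.

## Masks, regions, LPM

NAWM = (WM − WMH) eroded twice with the 6-connected element (the most
conservative reading of "two voxels in three dimensions"). Quartile
boundaries are the 25/50/75th percentiles of FW over the subject's lesion
voxels, intervals closed above so boundary ties fall to the lower quartile;
with continuous FW maps ties are measure-zero, and the all-equal edge case
puts every voxel in FWq1 by convention. Regional means exclude and count
non-finite voxels. Lesion probability maps are plain voxelwise averages of
binary masks on the shared grid; the peak cluster is the largest
26-connected component within 10⁻⁹ of the peak, matching common cluster
reporting.

## Statistics

* Paired t on WMH-vs-NAWM regional means (scipy), with the degenerate
  zero-variance cases handled explicitly.
* One-way MANOVA across FWq1–FWq4: Pillai's trace via statsmodels, and for
  each metric the univariate F plus generalized eta squared, which for this
  one-way between-groups design is SS_between/(SS_between + SS_within),
  computed from explicit sums of squares. The four subregions are in truth
  repeated measures within subject; the between-groups analysis is the
  study's stated design and is implemented as such. Post hoc: all six
  pairwise t contrasts per metric, Bonferroni-multiplied by six.
* Pearson and partial correlations; the partial coefficient correlates
  least-squares residuals on [1, covariates] with df reduced accordingly.
  The Bonferroni family is the set of pairs passed in one call (one
  figure-panel family) — a deliberate, configurable choice.
* Logistic regression with change-in-estimate selection: candidates are
  added in the caller-specified order to the current working model
  (sequential comparison base; a crude-base variant is a one-line change);
  a candidate is retained when the exposure OR moves by ≥ 10%. Wald 95% CIs
  on the log-odds scale; pseudo-R² is Nagelkerke (the flavor is pinned
  here because study reports rarely name it). Separation is detected by a
  saturated fitted log-odds check (|Xβ| > 30), which is scale-free.
* Cohen's kappa from the 2 × 2 agreement table with the large-sample
  standard-error CI, undefined (and rejected) when both raters are constant
  and equal.

## Pipeline

Stages run in order with per-stage timing and structured status; the voxel
models' regional table is cached on disk keyed by a configuration hash, so
statistics can be rerun without refitting. A cohort below four subjects
skips the statistics stage with an explicit "insufficient subjects" status.
Individual statistical analyses may legitimately fail on small cohorts
(e.g. separation in a 20-subject logistic model); those failures are
recorded per analysis in the run report rather than aborting the run, while
infrastructure failures still halt with the offending stage and subject
named.

## Problem sizes

The validation suite and the reproducibility script use: 1000 voxels for
the noiseless tensor-inversion check, 500 voxels for free-water recovery,
100 random coefficient vectors for the AFD–quadrature identity, 200 random
mask pairs, 100 + 200 simulated cohorts of n = 200 for the
change-in-estimate checks, and a 20-subject phantom at SNR 40 for the
end-to-end directional findings. These sizes were chosen as the smallest
that make the binomial/stochastic margins comfortable.

## Known limitations

* The free-water stage's spatial regularization is a smoothing pass, not
  the original gradient-flow functional; absolute FW values in structured
  regions can differ from published implementations even when directional
  findings agree.
* At the highest FW quartile the tissue-signal fraction is small, so
  tissue-tensor metrics there are the least identifiable; recovered MDt
  flattens between FWq3 and FWq4 (the corresponding group contrast is also
  the one study reports leave unresolved).
* AFD inherits the l = 0 pedestal of hard-constrained deconvolution and the
  GM fraction is correspondingly conservative on single-shell data.
* The MANOVA treats subregions as independent groups by design; a
  repeated-measures analysis would be more efficient and is not provided.
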