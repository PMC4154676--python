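# Methods

## The problem

Resting-state fMRI connectivity compares the temporal correlation of BOLD
signals between brain regions across subject groups.  In-scanner head motion
contaminates these correlations: frame-to-frame displacement produces
intensity changes that are shared between regions and therefore inflate (or,
between distant regions, deflate) measured connectivity.  Crucially, rigid
head motion with a rotational component displaces different parts of the
brain by different amounts — displacement grows with distance from the
rotation axis — so the artifact is *regionally patterned*, and the pattern
is a subject trait.  When two groups differ in their typical motion pattern
(different rotation centres, not merely different amounts of motion),
edge-wise group comparisons acquire spurious differences that a global
motion covariate (mean framewise displacement) cannot remove.

## Displacement measures

Realignment yields one rigid-body transform `T_t` per frame (reference at
the mid-series frame, expressed about the world-coordinate origin).  For a
voxel at world position `x`:

* voxel-wise displacement: `d_t(x) = ||T_t^{-1} x − x||_2` (mm); the stored
  quantity is the absolute first temporal derivative
  `D_t(x) = |d_t(x) − d_{t−1}(x)|`, `D_0 = 0` (mm/frame);
* `FD(t)` = mean of `D_t` over the brain mask; `RD_r(t)` = mean over ROI `r`;
* `dRD_r` = time-average of `RD_r(t) − FD(t)` — the per-region, per-subject
  scalar used as a second-level covariate.  Subtracting FD removes the
  (large) common amplitude component, avoiding collinearity between regional
  covariates and mean FD.

Choices: the per-voxel norm is the Euclidean 3-vector norm (an `rms` option
divides by √3); the derivative is stored unsigned by default (a signed
option exists for diagnostics); a `frame_to_frame` option measures
`||T_t^{-1}x − T_{t−1}^{-1}x||` directly, which upper-bounds the derivative
of the distance-to-reference.  Weighted aggregation identities (voxel-count
weighted RD = FD; weighted dRD sums to zero over a partition) are enforced
by tests.

## BOLD change and coupling

`DVARS(t)` is the RMS over voxels of the frame-to-frame intensity
difference; `RDVARS_r(t)` its per-ROI analogue, both computed on realigned
data before confound regression and filtering, with frame 0 set to zero and
excluded from correlations.  Residual measures `rRD = RD − FD` and
`rRDVARS = RDVARS − DVARS` isolate the regional component of the
motion–BOLD relationship; their correlation (pooled over regions and frames
per subject; a per-region-average option exists) quantifies regional
coupling, and plotting it against each subject's FD–DVARS correlation shows
whether the regional effect scales with the global one.

## ROI definition

Atlases are built from per-region probability maps: a voxel is labelled
with the argmax-probability region among those whose probability strictly
exceeds the threshold (default 25%; ties to the lower region id).  Regions
below a minimum volume (default 30 voxels; the unit is configurable to mm³)
are absorbed into the face-adjacent neighbour sharing the largest boundary
surface — ties to the larger neighbour, then the lower id — iterating until
no undersized region remains, with voxel-count conservation and provenance
recorded in the region table.  A declarative merge recipe (named source
regions → named target) covers atlas families whose customary merges are
known; the packaged recipe targets the Harvard-Oxford cortical/subcortical
naming and is a no-op on any other atlas.

## Denoising and connectivity

Nine first-level nuisance strategies are implemented (none; WM+CSF means
after one-voxel 6-connectivity erosion; global signal; 5-component CompCor
from the lowest-tSNR 2% of voxels — fraction configurable, as the canonical
threshold is a free choice; each ± 6 rigid motion parameters; and the
36-parameter expansion: 9 core regressors, backward differences, squares of
both).  Residualisation is OLS against the regressors plus intercept
(constant-zero and collinear columns dropped with warnings), followed by a
zero-phase (forward–backward) 4th-order Butterworth band-pass, 0.01–0.1 Hz.
Zero-phase filtering is used to avoid phase distortion of correlations; the
effective attenuation is the squared magnitude response.  Regression
precedes filtering by default (`filter_first` switches the order).
Connectivity is the Fisher-Z transformed Pearson correlation of denoised
regional time courses, with r clipped to ±(1 − 1e−7) before atanh; no
spatial smoothing exists anywhere in the pipeline (deliberately, to avoid
inflating neighbour correlations).

## Group-level models

Per edge (A, B), across subjects:

* STD:      `Z = b0 + b1·GRP + b2·age + b3·IQ + b4·gender + b5·meanFD + e`
* STD+RDI:  STD + `b6·dRD_A + b7·dRD_B + b8·dRD_A·dRD_B`

Gaussian GLMs fitted by IWLS reduce to ordinary least squares, which is
computed in closed form (normal equations); the statsmodels IWLS route
serves as an independent cross-check in the tests.  The effect of interest
is the group coefficient (t = β̂/SE, two-sided p at the residual dof).  The
three RDI terms are assessed jointly by a nested F-test on group-excluded
variants of the two models (F(3, n − p)); a pooled model concatenates all
edges of all subjects into one design whose interaction term characterises
the overall effect (within-subject edge dependence is ignored by
construction — the pooled p-value is descriptive).  The VIF of the grouping
factor (1/(1−R²) against the other non-intercept covariates) is reported
per edge to monitor collinearity between GRP and the motion covariates.
Multiple testing across edges uses Benjamini–Hochberg q-values (chosen over
local-fdr estimation for determinism and transparency); thresholded results
(p < 0.01 or q < 0.05) form statistical parametric networks exported as
TSV/GraphML.  Exact-interpolation fits (RSS ≤ 1e−12 of the response sum of
squares) are flagged rather than silently reported.  Age and IQ enter
unstandardised (standardisation would change only coefficient scale, not
test statistics).

## Cohort machinery

Subjects with mean FD > 0.7 mm are excluded (strict inequality).  To build
group pairs with controlled motion-pattern similarity, the cohort is
randomly halved repeatedly (odd cohorts put the extra subject in group 1);
for each split, ρ_groups is the spatial Pearson correlation between the two
halves' group-mean temporally-averaged displacement maps over mask voxels
(no standardisation).  Pairs nearest to requested ρ targets are selected;
a two-sided label-permutation test checks equality of group mean FD, using
exhaustive enumeration when the number of relabellings is ≤ 20000 and the
add-one Monte-Carlo estimator otherwise.

## Synthetic cohorts

The generator emulates exactly the conditions the framework is meant to
handle; it is first-class, tested code.

* **Motion.**  Six AR(1) parameter series (φ = 0.95; innovation scales
  0.0012 rad / 0.035 mm per unit amplitude) composed into rigid transforms
  about a subject-specific rotation centre, re-expressed about the world
  origin, mid-series frame forced to identity.  Motion is a trait: each
  subject draws a lognormal amplitude multiplier (log-SD 0.35) and a
  rotation-centre jitter (SD 10 mm) around the group phenotype.  Defaults
  give cohort mean FD ≈ 0.05–0.08 mm, matching low-motion cohorts of the
  kind studied in motion-artifact work.  Group phenotypes differing only in
  rotation centre (±40 mm along x) produce matched FD distributions but
  distinct spatial displacement patterns — the confound of interest.
* **Phantom.**  Ellipsoidal brain on a 24³ grid of 3-mm voxels; the
  grey-matter shell is partitioned into M = 20 contiguous parcels (Voronoi
  cells of k-means centroids on voxel coordinates; convexity of the cells
  within the convex mask guarantees contiguity); two solid off-centre balls
  act as white-matter and CSF compartments thick enough to survive erosion.
* **BOLD.**  Regional latent signals with a specified correlation matrix
  (default exchangeable r = 0.2), band-limited to 0.01–0.1 Hz *before*
  mixing so the band-pass stage cannot destroy planted structure, broadcast
  to voxels (amplitude 1), plus the motion artifact γ·D_t(x) (optionally
  with random per-voxel sign) and i.i.d. Gaussian noise (SD 1) on a baseline
  of 1000.  The additive displacement-coupled term is the simplest mechanism
  consistent with the observed FD–DVARS and rRD–rRDVARS coupling.  The
  coupling γ = 20 BOLD units per mm/frame is a free knob of the simulator
  (no quantitative value is derivable for real data); it was fixed so that
  the artifact contributes a realistic ~5% of ROI-signal variance yet
  remains detectable at the reduced simulated scale.  Group differences are
  planted by shifting chosen latent correlations on the Fisher-Z scale
  (nearest-PSD repair afterwards).
* **Determinism.**  Every subject-level RNG is seeded from the cohort seed;
  the manifest records all derived seeds, and regeneration is bit-identical.

### What the generator does *not* emulate

Hemodynamic response shape, physiological (cardiac/respiratory) noise,
scanner drift, spatial noise correlations, sub-TR intra-volume motion and
susceptibility distortion are absent.  Passing tests therefore demonstrate
that the pipeline's mathematics and the RDI mechanism behave as designed
under the planted artifact model — not that RDI removes every motion effect
in real data, where the displacement–BOLD coupling is more complex.

## Problem sizes and numerical choices

Cohort-level validation uses 2×30 subjects, 20 regions, 150 frames at
TR = 2 s on a 24³ grid — large enough for the edge-wise GLMs (60 subjects
vs 9 parameters) while keeping a 50-cohort replication affordable; the
test suite replicates 50 confound cohorts, 20 matched null cohorts and 20
preservation cohorts.  Unit tolerances: rigid-matrix orthonormality 1e−6 on
loaded text matrices (construction-level series satisfy 1e−8); oracle
agreement 1e−10 (displacement, metrics) and 1e−8 (GLM coefficients);
correlation clipping 1e−7; degenerate-fit flag at RSS ≤ 1e−12·TSS.
Tie-breaks are deterministic throughout (argmax takes the lower region id;
merge targets prefer larger shared boundary, then larger neighbour, then
lower id).

## Known limitations

The pooled interaction model ignores within-subject dependence between
edges.  Because the artifact's effect on Fisher-Z is nonlinear in a
subject's overall motion amplitude while the model's mean-FD covariate is
linear — and ΔRD is FD-subtracted, hence deliberately blind to global
amplitude — amplitude-composition imbalance between randomly formed groups
leaves a small residual artifactual difference that hits many edges of a
cohort at once; matched-motion comparisons are therefore slightly
over-dispersed relative to an independent-edge binomial null whenever the
coupling is active (the corresponding validation test documents this).  dRD collinearity with the grouping factor rises as group motion
patterns diverge (VIFs of ~5–10 occur in the deliberately extreme synthetic
contrast, versus ~1 in realistic matched groups); the RDI correction is a
second-level method and is not suitable for single-subject or very small
samples.  The displacement measures are "apparent": any realignment error
propagates into them.  Sub-TR motion is not modelled.
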