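# Methods

This note documents the models, numerical choices and limitations behind
`zmapsoz`. It describes what the code computes and why the defaults are what
they are; every empirical figure quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## The analysis model

The pipeline estimates, per cortical vertex, how far a patient's metabolism
falls below a healthy-control population, and evaluates the lowest 0.5 % of
cortex as a candidate seizure-onset marker against SEEG.

**Preprocessing (volume domain).** The anatomical volume defines the
reference grid. Skull stripping uses adaptive thresholding: the volume is
smoothed with a σ = 2 mm Gaussian and thresholded at 0.4 × the robust maximum,
where the robust maximum is the 99th percentile of the smoothed volume (the
reference statistic for the "intensity coefficient" is otherwise unspecified;
the 99th percentile is robust to hot-spot outliers). The largest connected
component is kept and interior holes filled. PET-to-anatomy registration is a
12-degree-of-freedom affine (translation, rotation, scale, shear; composition
order T·Rz·Ry·Rx·Shear·Scale, documented in `AffineTransform`) optimized by
multi-start Nelder–Mead over a two-level image pyramid with normalized
cross-correlation (NCC) as the similarity; a rigid 6-dof mode is available
for CT-to-MR style problems. Rotation/scale/shear act about the fixed image's
foreground centroid so that the translation parameters stay interpretable.
Registration quality is gated at NCC > 0.85; a failed gate is reported and
aborts the pipeline, never silently passed.

**Partial volume correction.** Van Cittert fixed-point deconvolution
f_{k+1} = f_k + α (g − h⊗f_k), f_0 = g, with h an isotropic Gaussian PSF.
Defaults: PSF FWHM 5 mm (the scanner-resolution figure the model assumes),
α = 1.0, 10 iterations — standard textbook settings, all exposed in the
config. Negative intensities are clamped to zero after each step and a
divergence guard stops the loop if the residual norm grows twice in a row.
On the phantom, 10 iterations reduce RMSE to the true activity to ~0.62 of
the blurred input's RMSE.

**SUVR and surface projection.** PET is converted to standardized uptake
value ratios by dividing by the mean uptake in the cerebellum mask. Vertices
are sampled at 50 % cortical depth: sample point = vertex − 0.5 · thickness ·
outward normal (the inward direction is −normal; the convention is pinned by
a linear-field exactness test). Trilinear interpolation; vertices leaving the
field of view are flagged missing, and >10 % missing is treated as a
surface/volume geometry mismatch. Pipeline order is PVC → SUVR → projection;
SUVR is a global division, so the order relative to PVC only matters through
the reference-mask blur, and both orders are available by composing the
library functions directly.

**Surface smoothing.** Geodesic Gaussian smoothing is approximated by
iterated neighbor averaging: each step replaces a vertex value by the mean of
itself and its mesh neighbors. One step spreads mass with 1-D variance
v₁ = k/(k+1) · h²/2 (k = mean vertex degree, h = mean edge length), so a
kernel of width σ = FWHM/2.3548 needs m = round(σ²/v₁) iterations. The scheme
exactly preserves the (1+degree)-weighted mean — hence the area-weighted mean
to <0.5 % on near-uniform meshes — and leaves constant maps untouched. On an
icosphere the measured FWHM of a smoothed delta is within ~12 % of the
request (tested at a 25 % tolerance); the kernel is not exactly Gaussian, and
accuracy degrades on meshes with strongly non-uniform edge lengths.

**Template and Z-map.** Control maps are globally mean-normalized (divided by
their cortex-mask mean) to remove intersubject metabolic scale; the template
stores the per-vertex sample mean and sample SD (n−1 denominator, the
unbiased choice at cohort size 23). Z = (x − μ)/σ per vertex; vertices whose
template SD falls below 10⁻⁶ of the template mean scale are flagged missing
rather than producing infinities. Calibration: a held-out control from the
same noise model scores mean ≈ 0 (|mean| < 0.05) and SD ≈ 1.01–1.02 on a
100-subject template — slightly above 1 because the template mean and SD are
themselves estimated (the √(1+1/n) inflation and finite-sample SD noise).

**Selection and region naming.** The hypometabolic set is the
k = max(1, ⌊fraction · n_usable⌋) lowest-Z vertices, fraction 0.005 by
default, computed jointly over both hemispheres (a per-hemisphere variant is
a one-line change via the mask argument); ties at the cutoff break toward the
lower vertex index, and missing vertices are excluded from numerator and
denominator alike. A region is hypometabolic iff ≥ 1 selected vertex carries
its label (no minimum-vertex rule; the natural reading of a bottom-fraction
overlay). Threshold overlays (vertices with Z strictly below a display
threshold) are exported for external surface viewers.

**Electrode localization.** A contact is a 0.8 mm diameter × 2 mm cylinder.
Its footprint is the set of label-volume voxels whose centers fall inside the
cylinder (voxel-center convention, 0-based indices, world = affine · index).
When fewer than 8 voxel centers are captured — any clinical-resolution grid —
candidate voxels are subdivided 4× per axis and fractional occupancy weights
are used, which keeps the >50 % rule meaningful on coarse grids. The contact
is verified gray matter iff one cortical region holds strictly more than half
of the total footprint; the denominator includes all labels (white matter and
background), so a contact straddling gray and white fails unless the gray
share itself exceeds 50 %. Exact 50/50 ties fail (strict inequality).

**Concordance.** The evaluation unit is the region instance: one distinct
(patient, hemisphere, region) carrying ≥ 1 verified contact. An instance is
SOZ-positive if *any* of its contacts is flagged as onset (the any-contact
rule; a majority-contact variant would only need a different reduction in
`build_region_instances`, and the choice is recorded in the output metadata
by construction). TPR/TNR/PPV/NPV/ACC and Cohen's kappa are computed per
stratum (total, five lobes, two hemispheres). Undefined metrics (zero
denominators, p_e = 1 for kappa) are NaN and named in an `undefined` list —
never coerced to zero, which would corrupt stratified tables. Strata with
fewer than 30 instances (configurable) are flagged `insufficient` and report
no numbers, mirroring the practice of excluding sparsely sampled lobes from
statistical reporting.

**Atlas lookup.** The bundled table maps the 74 standard Destrieux region
names per hemisphere to five lobes with totals 28/11/14/13/8
(frontal/parietal/temporal/occipital/insular). The atlas itself does not
define lobes; peri-rolandic and limbic regions straddle classical boundaries,
so the assignment places the central sulcus and cingulate structures with the
frontal lobe and the paracentral/marginal structures with the parietal lobe
to realize those totals. Published descriptions of this breakdown also
mention one unclassified region even though the five counts already sum
to 74; the table keeps the five counts and classifies all 74.

## The synthetic data model

The generator produces the study conditions the analysis assumes, with full
determinism under one seed (independent named substreams per component).

* **Surfaces.** Subdivided icosahedra (10·4ⁿ+2 vertices) deformed to
  ellipsoids, with analytic outward normals and a smooth random thickness
  field in [2, 4] mm (inside the anatomical 1.5–4.5 mm range). The phantom
  uses spherical hemispheres (radius 22 mm, centers ±21 mm) so ribbon depth
  and normals are exact; `make_toy_surface` itself defaults to a genuine
  ellipsoid. A vertex-correspondence interface (`project_to_template`)
  accepts real template-resampled data later.
* **Parcellation.** Geodesic Voronoi growth from random seed vertices gives
  edge-connected patches covering every vertex (12 per hemisphere by
  default); lobes are assigned geometrically (anterior → frontal, posterior →
  occipital, middle band split superior/inferior into parietal/temporal/
  insular) with largest-remainder quotas proportional to the 28/11/14/13/8
  atlas breakdown, so all five strata are exercised.
* **Metabolic maps.** A smooth regional baseline (per-region levels drawn
  once in [5, 7] arbitrary uptake units, then lightly smoothed across
  boundaries) plus vertex-independent Gaussian noise with SD = 5 % of the
  local baseline — the simplest model that exercises the Z statistic; spatial
  noise correlation is deliberately absent (see limitations). Patients add
  lesion_effect × SD inside the planted regions; lesions are region-aligned
  because the evaluation unit is the region. At the default −3 effect the
  planted deviation calibrates to the requested effect within 5 % (Monte
  Carlo).
* **Phantom volumes.** 64³ grid at 1.5 mm: two hemisphere shells with a 3 mm
  gray ribbon over a white core, a brainstem cylinder joining them to a
  cerebellum sphere of uniform reference uptake (4.0), a dark skull shell,
  and T1-like anatomical contrast (white 120 > gray 100 ≫ skull 20, additive
  unit-SD noise). Gray-ribbon voxels take the region of the nearest surface
  vertex, so volume labels and surface parcellation agree by construction.
  PET = activity ⊗ Gaussian PSF (FWHM 5 mm), then pull-resampled through the
  inverse of the known aligning transform; `GroundTruth.true_affine` stores
  the transform registration should recover.
* **Contacts.** Straight electrodes enter at a region's mid-ribbon point
  along the inward radial direction (entry points are scanned so the first
  contact's neighborhood actually carries the target label — regions near the
  interhemispheric overlap would otherwise be probed through the opposite
  hemisphere), with 3.5 mm center-to-center pitch (2 mm contact + 1.5 mm
  gap); deeper contacts fall in white matter and correctly fail gray-matter
  verification. Ground-truth region per contact is the majority label over a
  dense in-cylinder point grid.

**What the defaults are, and why.** Control cohort n = 23 (the template
cohort size the analysis is designed around); 30 patients; noise SD 5 % of
baseline (mid-range for normalized FDG uptake across healthy cortex); lesion
effect −3 control-SD (a clearly pathological deficit, matching the "three
standard deviations below controls" reading threshold); PSF FWHM 5 mm;
misalignment (4, −3, 2) mm; 0.5 % selection; NCC gate 0.85; stratum floor 30.
Problem sizes (642-vertex hemispheres, 64³ phantom, 100 replicates in the
recovery experiment, a 10 242-vertex surface for Z calibration) were chosen
as the smallest scales at which the statistical claims are stable; the full
pipeline runs in ~10 s and the whole validation in about a minute on one CPU.

## What passing tests do and do not show

The synthetic model has independent Gaussian vertex noise, region-aligned
lesions, spherical geometry and mono-modal-friendly phantom contrast. Near-
perfect recovery (TPR = 1.0, TNR ≈ 0.99 at effect −3 over 100 replicates;
TPR ≈ 0.8–0.9 at effect −1) therefore demonstrates that the chain is
implemented correctly and is sensitive at the stated effect size — not that
clinical performance reaches those numbers. Real cortex adds folding,
spatially correlated physiological variability, partial-parcel lesions,
registration across genuinely different contrasts, and imperfect SEEG
sampling, all of which lower concordance.

## Numerical choices and edge cases

* FWHM = 2.3548 σ everywhere; smoothing kernels are scaled per axis by voxel
  size, so parameters are in world mm on any grid.
* Resampling is pull-based trilinear for intensities and nearest-neighbor for
  labels; resampling an integer label volume with trilinear interpolation is
  refused outright.
* NCC of a blurred PET against a sharp anatomical volume has its affine
  optimum at a slightly contracted scale (the blur halo rewards shrinking,
  ~3–10 % on the phantom); centering the scale/rotation parameters on the
  foreground centroid keeps the recovered translation accurate (~0.2 mm
  error) despite this. Matching the two images' PSFs before registration
  would remove the bias; it is left to the caller because it trades
  sharpness for symmetry.
* Selection rounding is ⌊·⌋ with a minimum of 1, ties by vertex index —
  deterministic and exactly testable (e.g. 819 vertices at fsaverage's
  163 842).
* Degenerate template vertices (SD below 10⁻⁶ of the mean scale) and
  unlabeled vertices are excluded with flags/warnings, never silently zeroed.
* Contact axis vectors off unit norm by more than 10⁻³ are renormalized with
  a warning; duplicate contact ids are an error.

## Known limitations

* No spherical registration, no realistic cortical folding, no DICOM, no
  deformable registration, no MRI-guided PVC variants, no scanner physics
  beyond the Gaussian PSF, no subcortical/hippocampal analysis (the cortical
  parcellation excludes them), and no confidence intervals on the concordance
  metrics.
* The neighbor-averaging smoother under-delivers FWHM by ~10 % on icospheres
  and is only as good as the mesh uniformity.
* The control noise model is spatially independent; adding correlated noise
  (e.g. smoothing the noise field) is a one-line extension but changes the
  effective number of independent vertices and hence tail behavior of the
  0.5 % selection.
* The region-to-lobe table is an authored approximation pinned to published
  per-lobe totals, not an atlas-official mapping (none exists).
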