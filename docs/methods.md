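# Methods

This package implements an along-tract ("tractometry") analysis of the
arcuate fasciculus (AF) as a tested pipeline, together with a synthetic
phantom generator that stands in for the subject MRI such a study
consumes.  The pipeline takes co-registered 3-D volumes — a streamline
visitation (tract density) map, DTI parameter maps (FA, MD, AD, RD),
fMRI activation Z-maps and lobar ROI masks — and produces per-segment
tract profiles, healthy-control (HC) normative ranges, abnormal-segment
counts per patient, hemispheric laterality indices, and nonparametric
group/correlation statistics.

## Spectral tract parameterization

The tract density map is thresholded at 10% of its global maximum (the
usual guard against sparse false-positive visitations), optionally
restricted to the compact white-matter core by removing voxels anterior
to `y_max` or inferior to `z_min`, and the surviving voxels are
connected into a neighborhood graph (26-connectivity by default; 6 and
18 available).  On the combinatorial graph Laplacian `L = D − A` the
eigenvector of the smallest non-zero eigenvalue — the Fiedler vector —
is the smoothest non-constant function on the graph and orders the
voxels along the dominant elongated direction of the shape.  The
smallest eigenvalue itself is 0 with a constant eigenvector and carries
no trajectory information, so "the first Laplacian eigenvector" can
only usefully mean the Fiedler pair.

Numerical choices:

* graphs up to 600 nodes use a dense symmetric eigendecomposition;
  larger graphs use shift-invert Lanczos (`eigsh`, σ = −10⁻³).  Either
  way the residual ‖Lv − λv‖ is verified against a 10⁻⁸ tolerance and
  the solver errors out rather than returning a degraded eigenpair.
* disconnected masks are reduced to their largest connected component
  with a logged discard fraction; if that component holds less than
  half the mask the parameterization refuses, since the input is then
  not a single tract.
* the eigenvector's arbitrary sign is fixed anatomically: with the
  default `frontal` anchor, the decile of voxels with the smallest
  coordinate must lie more anteriorly (greater world-y mean) than the
  decile with the largest, so segment 1 is always the frontal end.

**Arc-length linearization.** On an elongated domain the Fiedler vector
behaves like `cos(π s / L)` in arc length `s` (exactly so on a path
graph).  A plain min-max rescale of the eigenvector therefore crowds
voxels toward `t = 0` and `t = 1`, and equal-width segments would be
spatially unequal — the end segments several times larger than the
middle ones.  The normalized coordinate `u` is therefore passed through
`t = arccos(1 − 2u)/π`, which inverts the cosine exactly on a path and
leaves `t` approximately proportional to arc length in general.  The
transform is strictly monotone, so rank-based diagnostics (Spearman
recovery, segment ordering) are unaffected; it can be disabled
(`linearize=False`) to obtain the raw min-maxed spectral coordinate.
On the default curved phantom the linearized `t` correlates with the
true arc-length fraction at Spearman ρ ≈ 0.99998 and the 15 equal-width
bins of `t` all contain ≥ 20 voxels.

Segments are `label = ⌊t·K⌋ + 1` with `t = 1` assigned to `K` (default
K = 15), i.e. equal-width bins on `t`, not equal-count quantiles.

The anterior/inferior core limits are pure configuration with both mm
and voxel-index modes.  Published values of `y_max = 65` and
`z_min = 40` for this step are ambiguous between mm and voxel indices
of a template grid (as mm, `z ≥ 40` would remove most of the AF arch),
so no default is asserted: the pipeline default applies no core
restriction to the phantom, and real analyses should set the limits
for their template explicitly.

## Per-segment profiles

Within each segment the **median** of each DTI map over the segment's
voxels forms the profile value; the median keeps single hot voxels
(partial-volume CSF, registration artifacts) from dragging a segment.
Non-finite voxels are excluded rather than propagated, because
registration padding produces NaN borders in real data; an entirely
empty segment yields an explicit missing value.  Diffusivities are in
10⁻³ mm²/s throughout, FA is dimensionless.

## Normative model

`NormativeRangeModel` is fitted per DTI parameter and hemisphere from a
(subjects × segments) HC matrix:

1. **De-median**: the across-subject median `m_k` is subtracted per
   segment, pooling all segments onto one distribution of deviations.
2. **Outlier trimming**: pooled deviations beyond `3 ×` the **mean**
   absolute deviation about the median are removed.  The mean absolute
   deviation is implemented literally (not the conventional
   median-based MAD); `mad_kind="median"` switches.  For Gaussian data
   the threshold sits at 3·√(2/π) ≈ 2.39 SD and trims ≈ 1.7% of values
   (≈ 8 of 480); real cohorts showing 2–4% removal are slightly
   heavier-tailed than Gaussian.
3. **Band**: the 2.5th–97.5th percentile interval is estimated
   parametrically as `m_k ± 1.959964 σ`, with σ the standard deviation
   (about the mean, ddof = 1 — both are config) of the kept deviations.

Patient segment medians strictly below the band are `low`, strictly
above `high`; boundary values are normal (strict inequalities).  No
trimming is ever applied to patients: out-of-range values are the
signal.  Per-subject summaries count the injury-signature directions —
decreased FA/AD, increased MD/RD — alongside two-sided abnormal sets
and across-segment medians.

**Known calibration bias.** Because σ is estimated *after* trimming, it
estimates the SD of a truncated normal (≈ 0.943 of the population SD
under Gaussianity), so the nominal 95% band covers ≈ 93.5% of the
population; finite-sample error in the per-segment medians (32
controls) lowers in-sample coverage by a further ≈ 0.5 points, to
≈ 93% as measured by the acceptance script.  This is a property of the
estimate-SD-after-trimming procedure itself, not of this
implementation; it slightly inflates abnormal-segment counts
symmetrically for all subjects and does not affect group contrasts.

## Laterality index

Activation maps are thresholded at `Z > 3.1` (strict; `strict=False`
gives ≥) and suprathreshold voxels are counted inside homologous
left/right ROI masks.  `LI = (L − R)/(L + R)` per lobe: +1 fully
left-lateralized, −1 fully right, undefined (explicit NaN) when no
voxel is active on either side.  Homology is supplied as explicit mask
pairs so any parcellation works; no dead-band is applied (LI > 0 reads
leftward, LI < 0 rightward).

## Statistics

Cohorts in this setting are tiny (4 vs 5 patients), so:

* **Mann–Whitney U** uses the exact permutation null — the distribution
  of U over all C(n₁+n₂, n₁) assignments of the observed pooled values,
  computed tie-safely by a dynamic program over doubled mid-ranks
  (identical to full enumeration, verified against it in tests).
  Two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))); this reproduces
  p = 1 for a perfectly centered U.  Beyond combined n = 25 the
  tie-corrected normal approximation is used and recorded.
* **Benjamini–Hochberg**: step-up adjusted q-values
  `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1; thresholding `q < α`
  equals the classic step-up rejection set.  Findings are declared at
  FDR < 0.1, appropriate for cohorts under 20 subjects.
* **Spearman**: Pearson correlation of mid-ranks; the two-sided p is
  exact by full permutation for n ≤ 9 and the t approximation with
  n − 2 df otherwise (the approximation is what commercial packages
  report at these sizes; both are available and the method used is
  recorded per row).

## Synthetic phantom

The generator emulates the study's inputs with known ground truth:

* **Geometry**: a C-shaped centerline (chord-length cubic spline
  through 7 control points in one sagittal plane, arching
  frontal → temporal) rasterized as a tube of radius 4 mm with Gaussian
  density falloff (scale 2 mm) on a 64³ grid at 2 mm isotropic spacing
  — the smallest grid on which all 15 segments hold ≥ 20 voxels.  The
  affine is RAS with the grid centered on the origin, so the left
  hemisphere is unambiguously x < 0.  Every in-tube voxel records the
  arc-length fraction of its nearest centerline sample as ground-truth
  `t`.
* **DTI cohorts**: FA, AD and RD fields are baseline + a global
  per-subject offset + smoothed spatial noise (white Gaussian, 2-voxel
  kernel, renormalized to unit per-voxel SD); the variance is split
  50/50 between offset and noise so the total per-voxel SD equals the
  declared between-subject SD (FA 0.02, AD 0.04, RD 0.04).  MD is
  derived as (AD + 2 RD)/3, so maps are always tensor-consistent.
  Baselines default to HC along-tract medians typical of the AF
  (FA 0.43, AD 0.88, MD 0.587, RD 0.44; configurable).
* **Lesions**: patients receive additive offsets on voxels whose
  ground-truth segment is lesioned.  Defaults are taken from the
  extremes of patient-group ranges relative to HC medians — high-grade:
  ΔAD +0.11, ΔRD +0.14, ΔFA −0.07, ΔMD derived (+0.13); low-grade at
  half amplitude — and are configurable.  Values pushed out of the
  physical range (FA outside (0,1), diffusivity ≤ 0) are clamped with a
  logged warning.
* **Z-maps**: suprathreshold voxels are placed inside paired lobar
  masks so the realized voxel-count LI matches a target up to integer
  rounding; the background stays strictly below threshold.
* **Profile-level simulators** mirror the volumetric generative model
  directly at the segment-median level (baseline + subject offset +
  per-segment noise) for Monte-Carlo calibration studies where
  rasterizing volumes would add nothing.

What the phantom does **not** emulate: raw diffusion signals and tensor
fitting, registration error, tumor mass effect and anatomical
distortion, spatially structured (non-stationary) noise, realistic
fMRI time series.  Passing tests therefore demonstrate the correctness
and calibration of the *analysis* under its own assumptions, not
robustness to acquisition artifacts.

## Pipeline and reproducibility

`RunConfig` is the single source of truth for every tunable (K = 15,
10% density threshold, Z > 3.1, FDR 0.1, 3×MAD factor, 1.96 SD band,
cohort sizes, seeds); `run_pipeline` writes all stage TSVs plus a
manifest with the config hash, seeds, library versions and stage
wall-times.  Two runs with the same config are byte-identical.  The
default configuration mirrors the study conditions (32 HC, 4 low-grade
and 5 high-grade patients, both hemispheres) and completes in well
under a minute; tests and the acceptance script use reduced cohorts
(e.g. 12 HC for the volumetric lesion-recovery check, profile-level
simulators for 100-seed Monte-Carlo loops) chosen so the statistical
assertions keep comfortable margins.

Group laterality targets for simulated patients default to the
left-dominant low-grade / rightward-parietal high-grade pattern
(frontal/parietal/temporal LI of 0.30/0.37/0.36 vs 0.02/−0.18/0.33,
with ±0.10 per-patient jitter), which reproduces the expected negative
correlation between parietal LI and abnormal MD/RD segment counts.

## Limitations

* The voxel-adjacency graph is a discrete stand-in for a triangulated
  surface mesh of the tract volume; on tube-like masks the two agree in
  their leading non-trivial eigenvector, but no equivalence is claimed.
* The normative band's ≈ 93% effective coverage (above) means absolute
  abnormal-segment counts run slightly high relative to a nominal 95%
  band; comparisons between groups are unaffected.
* The laterality index depends on the Z threshold; no threshold-robust
  LI curve is computed.
* Which hemisphere's tract enters a patient's summary metrics is a
  config choice (default: tumor-ipsilateral).
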