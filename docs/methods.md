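# Methods

## Scope and assumptions

The pipeline analyses diffusion tensor data that are already in one common
(atlas) space: motion/eddy correction and nonlinear registration are out of
scope, and all subjects are assumed voxel-wise comparable.  Bundle geometry
is computed once on the *cohort-averaged* data (the tensor field fitted to
the mean of the control DWIs), so every subject's profiles are sampled along
the same mean curve — the design that keeps pointwise statistics anatomically
aligned across subjects and restricts the bundle to the region where
subjects overlap.

## Acquisition model and tensor estimation

The simulated acquisition is 1 baseline (b = 0) plus 15 diffusion-weighted
volumes at b = 800 s/mm².  The 15 unit directions are a fixed
electrostatic-repulsion set (antipodally symmetric energy, minimum pairwise
angle 36.9°), hard-coded for reproducibility.  The forward model is the
single-tensor signal equation `S = S0 exp(-b g^T D g)`; magnitude noise is
Rician, `sqrt((S+ε1)² + ε2²)` with `ε ~ N(0, (σ·S0)²)`, σ expressed as a
fraction of the baseline signal (default 0.03, i.e. baseline SNR ≈ 33,
typical of single-shot EPI at 3 T).

Tensors are estimated by unweighted log-linear least squares over the six
unique coefficients; multiple b = 0 volumes are averaged into S0 first.
The estimator is deterministic and closed-form, which makes the noise-free
round trip (simulate → fit) exact to ~1e-16 relative and easy to verify.
Voxels with S0 ≤ 0 receive a zero tensor and an `invalid` flag.  For the
scalar maps, negative eigenvalues (possible in noisy background voxels) are
clamped to zero and flagged; without clamping, background FA can exceed 1.

## FACT tracking

Propagation follows the original nearest-voxel fiber-assignment scheme:
the direction is the principal eigenvector of the voxel the track currently
occupies, updated at each voxel entry, with polyline vertices at the
voxel-boundary crossings.  The eigenvector sign is chosen to continue the
incoming direction; seeds launch both signs and the two half-tracks are
merged.  Termination: entering a voxel with FA below the threshold (default
0.15), a turning angle above the threshold (default 50°), or leaving the
grid.  Streamlines shorter than 10 mm (configurable) are discarded to
suppress single-voxel fragments.  Tracking is exactly reproducible — there
is no randomness and no interpolation of directions (the interpolated /
Runge-Kutta variant is deliberately out of scope).

ROI selection voxelizes each streamline by dense sampling (< half-voxel
steps) and keeps the streamlines whose voxel sets intersect *every* ROI.
Planar ROIs fix one axis (sagittal = x, coronal = y, axial = z) with an
optional in-plane rectangle.  The slice indices of the published
fornix/cingulum delineation protocol for 1 mm atlas-space data ship as
`limbictract/data/mori_roi_protocol.yaml`; the tests use analogous planes
on phantoms.  The volume-overlap reliability measure is Dice
`2|A∩B|/(|A|+|B|)` by default with Jaccard behind a flag — the published
87.5% figure for fornix extraction does not state its formula, so neither
variant is treated as reproducing it.

## Mean curve and profiles

Instead of a diffeomorphic (LDDMM) curve-matching mean, the bundle's
geometric representative is built by a deterministic construction: orient every streamline so its first point is
nearer a chosen origin ROI, resample each to 30 equal-arc-length points,
average coordinates pointwise across streamlines, and re-parameterize the
average to exactly 30 uniform arc-length points.  On coherent, consistently
oriented bundles the two constructions agree; the substitution trades the
diffeomorphic machinery for something oracle-testable (on tube phantoms the
mean curve stays within 0.2 mm of the true centerline, versus the 1-voxel
acceptance bound).  The stored arc-length parameterization refers to the
averaged source polyline, hence is uniform by construction; for smooth
curves the chord lengths of the 30 stored points agree with it to ~1e-9.

Per-subject profiles are trilinear interpolations of the subject's scalar
maps at the 30 shared curve points (sampling, not per-streamline
projection, since subjects share the atlas frame; trilinear interpolation
reproduces affine fields exactly, which the tests exploit).  Profile ends
that touch a bundle's boundary mix with background by construction of the
interpolation — a known partial-volume effect visible at the two cap points
of tube phantoms.

Smoothing replaces each point by the mean over itself and its five nearest
neighbours along the curve index; the tie between the two candidates at
distance 3 goes toward the curve start, so the interior window is
`{i−3, …, i+2}` (divisor 6), truncated to available indices at the
boundaries.  The alternative reading — averaging the five neighbours
without the centre (divisor 5) — is available via `include_center=False`.
The asymmetric window shifts a linear profile by half a step; for the
hypothesis tests that matter (group differences, correlations) the same
window is applied to every subject, so the shift cancels.

## Statistical model

Group comparisons are OLS of the (smoothed) metric on
`[intercept, group, age, education, illness duration]` with group coded
control = 0 / patient = 1 (a positive RD coefficient means higher RD in
patients) and two-sided p from the t distribution with n − 5 df.  Illness
duration is coded 0 for controls so a single model covers both groups; the
price is strong group–duration collinearity (r ≈ 0.7 in cohorts drawn from
the study demographics), which inflates the group coefficient's standard
error by roughly 1.4× — a real property of this covariate design, not an
implementation artifact.  Whole-bundle (ROI-level) regressions on the
per-subject profile means are reported uncorrected; the pointwise analyses
apply Bonferroni within each bundle × metric over the 30 arc-length points
(the family size is a configuration knob, default 30; the alternative of
correcting across bundles and metrics as well is stricter and can be had by
setting the knob accordingly).

Clinical associations use partial correlations: both variables residualized
on `[intercept, age, education, duration]` by least squares, Pearson r of
the residuals, `t = r sqrt((n−2−k)/(1−r²))`.  They are computed in patients
only (controls have no symptom scores) with the same per-bundle Bonferroni
family.

## Synthetic cohorts

Phantoms are tubes around a parametric centerline: voxels whose centre lies
within the tube radius get eigenvalues (1.5, 0.3, 0.3)×10⁻³ mm²/s with the
principal axis along the local tangent; the background is isotropic
0.7×10⁻³.  Tubes have flat end caps (voxels projecting onto a centerline
endpoint are excluded) so the tube's extent matches the ground-truth
centerline that tracking results are scored against.  Patients receive an
additive increase of the two minor eigenvalues inside a configurable
arc-fraction segment: RD up, FA down, AD unchanged — the fornix signature.
Each subject additionally gets a tube-wide Gaussian perturbation of the
minor eigenvalues (SD 0.02×10⁻³ mm²/s), the biological between-subject
variation to which clinical scores couple.

Covariates are drawn from the study's demographic distributions
(age 35.4 ± 8.82 control / 39.4 ± 8.82 patient; education 13.9 ± 2.50 /
11.6 ± 2.40; duration 12.7 ± 8.99 patients, 0 controls; PANSS subscales
10.1 ± 3.28 / 8.7 ± 2.68 / 19.9 ± 4.17; GAF 53.6 ± 17.5), with 31 controls
and 33 patients by default.  PANSS couplings are specified as target
correlations and act through the subject-level latent FA at the locus
(the midpoint of the effect segment).

For the replicated error-rate and power simulations a profile-level
generator draws the 30-point profiles directly:
`y_ij = baseline + group_i·δ_j + u_i + e_ij`, with a subject-level
intercept `u_i` and independent pointwise noise `e_ij`.  Its defaults —
total per-point SD 0.04 and a subject-level variance share (ICC) of 0.4 —
are the profile-level abstraction of the image model above: at Rician
σ = 0.03 and jitter SD 0.02×10⁻³ the image pipeline yields per-point FA SD
≈ 0.02 with inter-point correlation ≈ 0.41, and 0.04 is the realistic
per-point FA SD for in-vivo along-tract data (phantom profiles are cleaner
than real ones).  Clinical couplings state the target partial correlation
between the *raw* profile value at the locus and the score; because the
coupling acts through `u_i`, smoothing (which averages away `e_ij` but not
`u_i`) raises the observed correlation above the raw target — the same
mechanism that motivates smoothing real profiles.  A consequence worth
noting: the attainable raw-profile correlation is bounded by sqrt(ICC), so
couplings beyond ±0.63 are rejected as unattainable at the default split.

What the generator deliberately does *not* model: registration error and
inter-subject anatomical variability (all subjects share one grid), head
motion, eddy currents, susceptibility distortion, crossing fibers inside a
bundle, multi-shell acquisitions, and spatially varying noise.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to real-data confounds.

## Operating characteristics and problem sizes

With the defaults, simulation at the study's sample sizes gives
(analysis/06_error_rates.py): family-wise error ≈ 0.02 under the null
(≤ 0.05; Bonferroni is conservative because smoothing correlates
neighbouring points), recovery of a locus coupling with raw partial
r = −0.6 in ~100% of replicates, and a non-empty, correctly contained
flagged set for a d = 1.2 injected FA drop in ~80% of replicates.  That
last rate is power-limited: smoothing can only reduce the pointwise noise
share of the variance, and the covariate collinearity noted above costs a
further ~30% of effective noncentrality, so per-point power at α/30 sits
near 0.85 rather than ~1.  Larger effects (d ≳ 1.5) or a lower
subject-level variance share push the rate above 90%.

Replicate counts (500 for null error rates, 100 for power) and the phantom
grid (40×16×16 voxels of 2 mm) were chosen so the full suite and the
acceptance script each run in about a minute on one CPU while keeping
Monte-Carlo error on a 0.05-level rate below ±0.02.

## Numerical choices

* Eigendecomposition: `numpy.linalg.eigh`, eigenvalues re-sorted descending.
* Tensor fit: pseudo-inverse of the 6-column design, applied voxel-wise;
  signals clipped at 1e-12 before the log.
* Tracking: voxel-exit computed by ray-box stepping with an 1e-9 guard for
  axis-parallel directions; exact corner hits advance along the single
  smallest-exit axis; duplicate vertices are dropped.
* Resampling: linear interpolation of each coordinate against cumulative
  chord length; endpoints preserved exactly.
* Degenerate statistics: perfect fits (zero residual variance up to
  round-off) report t = 0, p = 1 when the coefficient is zero; partial
  correlations with (numerically) zero residual variance raise.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the cohort/pipeline configuration; identical configs are bit-identical.
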