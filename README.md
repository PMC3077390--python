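# limbictract

Along-tract ("tractometry") analysis of limbic white-matter bundles from
diffusion tensor imaging, built as a tested, reusable pipeline and exercised
end-to-end on synthetic diffusion phantoms with known ground truth.

The scientific question the pipeline serves: whole-bundle averages of
diffusion metrics wash out focal white-matter damage.  Studies of the fornix
and cingulum in schizophrenia instead profile fractional anisotropy (FA),
radial diffusivity (RD) and axial diffusivity (AD) *as a function of
arc-length position* along each bundle, and test for group differences and
clinical correlations point by point.  This package implements that whole
chain for data already in a common (atlas) space:

1. **Tensor fitting** — per voxel, ordinary log-linear least squares on
   `ln(S_i/S_0) = -b_i g_i^T D g_i`; eigenvalues `λ1 ≥ λ2 ≥ λ3` give
   `FA = sqrt(3/2)·‖λ − λ̄‖/‖λ‖`, `RD = (λ2+λ3)/2`, `AD = λ1`.
2. **FACT tractography** — deterministic fiber assignment by continuous
   tracking: nearest-voxel principal-eigenvector propagation, bidirectional
   from every seed voxel, stopping at FA < 0.15, turning angle > 50°, or the
   grid edge.
3. **Multi-ROI bundle extraction** — keep exactly the streamlines that
   penetrate every selection ROI (AND logic); the cingulum can be
   partitioned into anterior/middle/posterior sub-bundles at two coronal
   planes; Dice/Jaccard volume overlap quantifies extraction reliability.
4. **Mean curve and profiles** — each bundle is summarized by a mean curve
   parameterized at 30 equal-arc-length points; every subject's FA/RD/AD
   maps are sampled along the shared curve (trilinear interpolation) and
   smoothed by nearest-neighbour averaging along the curve.
5. **Statistics** — at each point, OLS of the metric on
   `[group, age, education, illness duration]` with Bonferroni control over
   the 30 points of a bundle-metric; partial correlations with PANSS scores
   (patients only) under the same correction.

Since no real scans ship with the package, `limbictract.synthetic` generates
the study conditions: curved-tube tensor phantoms, the 16-volume acquisition
(1 × b=0 + 15 directions at b = 800 s/mm²) with Rician noise, and cohorts of
31 controls / 33 patients whose group effect is confined to a known
arc-length segment and whose clinical scores are coupled to FA at a known
locus.  Every pipeline stage is validated against this ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a phantom
cohort (31 controls, 33 patients; patients' minor eigenvalues raised by
0.2×10⁻³ mm²/s in the middle fifth of the tract — the fornix signature of
RD up / FA down / AD unchanged; PANSS total coupled negatively to locus FA):

```sh
cd analysis
python 01_simulate_cohort.py   # cohort on disk: DWIs, bvec/bval, covariates
python 02_fit_tensors.py       # mean-DWI tensor, FA/RD/AD maps
python 03_track_bundles.py     # FACT + two-plane extraction + mean curve
python 04_along_tract_stats.py # ROI-level and pointwise group statistics
python 05_clinical_correlations.py
python 06_error_rates.py       # operating characteristics by simulation
```

Output of steps 03–04 on this cohort:

```
FACT: 384 streamlines from whole-grid seeding; 384 kept by the two-plane multi-ROI selection
mean curve: 30 points, length 64.0 mm
volume overlap with ground-truth tube: Dice 0.985, Jaccard 0.970

whole-bundle (ROI-level) group effects, uncorrected:
  bundle metric  coefficient         t        p
fornix_L     ad     0.000002  0.566247 0.573374
fornix_L     fa    -0.029052 -4.930550 0.000007
fornix_L     rd     0.000036  4.993865 0.000006

pointwise (tract-based) analysis, Bonferroni over 30 points:
  fornix_L/ad: 0 flagged points  (min p = 5.66e-02)
  fornix_L/fa: 9 flagged points [11, 12, 13, 14, 15, 16, 17, 18, 19] (min p = 4.14e-31)
  fornix_L/rd: 9 flagged points [11, 12, 13, 14, 15, 16, 17, 18, 19] (min p = 5.33e-31)

true effect segment: arc fractions (0.4, 0.6) ~ points 11-17
```

Reading: the whole-bundle analysis finds the expected signature (FA lower
and RD higher in patients, AD unchanged), and the pointwise analysis
localizes it — the flagged points cover the injected segment (11–17) plus
its smoothing halo, with nothing flagged elsewhere.  The extraction
reliability (Dice 0.985 against the true tube volume) is reported the way
bundle-segmentation overlap is usually quoted.

A `limbictract` console command exposes the same stages
(`simulate`, `fit-tensor`, `track`, …, `run-all`) over a YAML config; stages
are cached by content hash, so re-runs only recompute what changed.

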