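# Methods

This note records the models implemented by octaflow, the numerical
choices behind them, and what the synthetic-data experiments do and do
not demonstrate.

## Segmentation and centerlines

Vessels are separated from background by 1-D k-means on pixel intensity
(k = 2 by default). Centers are initialized evenly between the intensity
minimum and maximum and Lloyd iterations run to convergence, which makes
the clustering deterministic without a seed; the brighter cluster is
foreground. For a two-valued image this reduces to thresholding at the
midpoint of the two values. Intensity-only clustering deliberately uses
no spatial features: it is transparent, resolution-independent, and
sufficient for the high-contrast angiograms the pipeline targets.

The skeleton is the medial axis (distance-transform ridge) of the binary
map, 8-connected. Skeleton pixels with ≥ 3 skeleton neighbors in their
8-neighborhood are bifurcation points; removing them splits the skeleton
into simple paths, each ordered by walking from an endpoint. Two cleanup
rules matter in practice:

* the medial axis of a blunt vessel end sprouts short diagonal
  "fishbone" branches toward the corners; branches shorter than
  `min_length_px` that carry a skeleton endpoint are pruned *before*
  junction splitting, so a plain rectangular bar yields one
  uninterrupted axial centerline rather than a truncated one;
* after splitting, segments shorter than `min_length_px` (default 10 px,
  configurable) are discarded as spurs.

Cyclic skeleton components (rings without bifurcations) cannot be
ordered endpoint-to-endpoint and are skipped.

## Vessel tortuosity index

For one centerline, `VTI = 0.1 · SD_θ · N · M · L_A / L_C`. The
operationalization of the components on integer pixel paths is where the
real numerical decisions live:

**Path smoothing.** All geometry is measured on a centered moving
average (window 9 px) of the pixel path, with the original endpoints
kept fixed so the chord is unchanged. Rounded digital curves are
4-connected staircases; summing Euclidean steps along them inflates arc
length by up to 27% (a rasterized semicircle measures L_A/L_C = 2.0
instead of π/2 ≈ 1.571). With the 9-px smoothing the semicircle ratio is
recovered to 0.3% and the index changes by under 1% when a test curve is
rotated by arbitrary angles and re-rasterized. Segments shorter than
twice the window pass through unsmoothed.

**Tangent angles.** At each interior point the tangent is the central
difference over ±2 points; its angle is measured against the
endpoint-to-endpoint chord and wrapped to (−π, π]. SD_θ is the
population standard deviation of these angles.

**Critical points.** N counts turning points of the signed
perpendicular deviation of the path from its chord, detected with a
0.5-px hysteresis: the profile must retreat at least half a pixel from
its running extremum before that extremum is counted. Half a pixel is
below the resolution of an integer-coordinate path, so quantization
ripple (which a naive sign-change rule counts as dozens of spurious
extrema) is ignored while genuine undulations of ≥ 1 px survive. A
straight segment has no critical points, hence VTI = 0 exactly.

**Amplitude.** M is the mean absolute deviation-profile value at the
critical points divided by chord length, making the index invariant to
uniform rescaling of the image.

Consequences verified by tests: VTI ≥ 0 with equality exactly for
segments without critical points; invariance under translation and (to
< 2%) under discretized rotation; strict monotonicity in sinusoid
amplitude at fixed period; and agreement to better than 1e-9 relative
with an independently written plain-loop implementation of the same
definitions on 50 random smooth centerlines.

## Local fractal dimension and density metrics

A 3 × 3 window admits exactly two box scales, so the per-pixel LFD is
the two-point slope `log N(1) / log w` with N(1) the foreground count in
the window (0 for an empty window): 0 for an isolated pixel, 2 for a
fully occupied window. Borders are zero-padded to preserve shape. The
FDR map divides by the global maximum (an all-zero map stays zero), and
the (VD, SSV, SLV) fractions count pixels in [0.7, 1], (0.3, 0.7) and
[0, 0.3] respectively — the band boundaries belong to VD and SLV. The
three counts partition the image by construction, so the fractions sum
to one for every input; on a uniform random FDR field they converge to
the interval lengths (0.3, 0.4, 0.3).

## Doppler flowmetry

The phase-resolved velocity relation is `v = λ·Δφ / (4π·n·τ)` with the
tissue group index n = 1.38; all constants live in `ScanMeta`
(defaults: 840 nm, 70 kHz, 80 × 500 A-scans over 2 × 2 mm). At these
defaults the phase wraps at ±10.65 mm/s; wrapped data are rejected, not
unwrapped, because no unwrapping convention is assumed. Flow on an
en-face plane is the velocity sum over the vein mask times the pixel
area (mm³/s ≡ µL/s, ×60 → µL/min); en-face planes are normal to the
beam, so the axial velocity component is exactly the flux-carrying one
and no Doppler-angle correction applies. Per vein the largest absolute
plane flow is recorded (the mid-lumen plane sees the full cross
section), reported positive under the venous sign convention; vein
maxima are summed per volume and averaged across volumes. Vein masks are
inputs; automated vein detection is out of scope.

## Synthetic data

The generators return their ground truth alongside the rendered data and
never recompute it from the output.

* **Sinusoid vessels** render a band of configurable amplitude, period,
  width and 5:1 contrast with additive Gaussian noise; the truth
  centerline samples the analytic curve once per column and bridges
  consecutive samples with Bresenham segments, guaranteeing a valid
  8-connected path.
* **Vessel trees** draw straight strokes with a circular brush from a
  branching frontier; the returned vessel fraction is the exact
  foreground mean of the rendered mask.
* **Flow phantoms** place cylindrical veins with parabolic (Poiseuille)
  profiles, chosen because the analytic flow `Q = v_peak·πR²/2` provides
  an exact oracle. Pixels store the profile averaged over a 4 × 4
  subpixel grid — the areal average a detector would report — which
  makes the discrete integral agree with the analytic flow to ~0.2%
  despite the strongly anisotropic 4 µm × 25 µm sampling. The profile is
  tapered axially so the mid-vessel plane carries the maximal flow.
  Default veins run at 5–8 mm/s peak velocity, inside the wrap limit of
  the default scan parameters. Phase noise is added per volume and
  re-wrapped into (−π, π].
* **Cohorts** sample eye-level metrics directly (no per-subject image
  rendering) as group mean + subject random effect + eye residual, with
  60% of each metric's SD at the subject level by default, exact
  per-group eye counts (15/26 from 12/19 subjects), exact sex and race
  tables, and MAP reconstructed from three simulated cuff readings. An
  optional coupling term adds a linear TRBF→metric slope per 100 µL/min.
  The defaults reproduce the study population's marginal means and SDs
  in expectation. `association_recovery_spec` builds the variant used
  for slope-recovery experiments: both groups share one outcome baseline
  and one TRBF distribution so the generating model coincides with the
  fitted association model and the coupling slope is the estimand; the
  default cohort, whose group baselines differ, would confound the
  group contrast into the slope.

What passing these experiments shows — and does not. The phantoms have
no speckle, bulk motion, projection artifacts or segmentation errors, so
recovery there validates the algebra and integration, not robustness to
instrument physics. Likewise the cohort generator draws Gaussian
metrics; it validates the inference machinery, not distributional
robustness.

## Mixed-model inference

Association and group models are linear mixed models with a random
subject intercept, fitted by REML (statsmodels `MixedLM`). Laterality
enters as a fixed binary covariate (OD reference) and MAP as a fixed
continuous covariate; the group contrast uses the control group as
reference. Covariates are standardized internally for optimizer
stability and the focus coefficient mapped back to its original scale,
which also makes predictor rescaling exact. After the gradient-based
fit, a gradient-free Powell refinement resolves boundary solutions: with
truly zero subject-level variance the fixed effects then match OLS to
~1e-11 relative. The Wald standard error is evaluated from the
closed-form GLS covariance at the REML variance estimates rather than
the optimizer's internal approximation, which can fail near the
boundary.

Degrees of freedom use the Satterthwaite approximation, computed from
the closed-form random-intercept REML curvature (numerical gradient of
the Wald variance and Hessian of the restricted log-likelihood in the
two variance components). In this design — most subjects contribute one
eye — simple df-counting rules fail in opposite directions: a
between-within rule assigns the eye-level predictor the within-subject
df (≈ 8 here), giving measurably conservative intervals, while the
large-sample normal approximation is anticonservative at 31 subjects.
Satterthwaite df (median ≈ 35 in the recovery experiments) keeps
empirical 95% CI coverage at 0.93–0.955 across replicate batches. If the
curvature computation is degenerate the residual df `n − p` is used.

Rank deficiency of the fixed-effects design raises an error naming the
collinear columns (QR with pivoting). Tests are two-sided at α = 0.05
throughout, with no multiple-testing correction, matching the analysis
plan the package emulates.

## Statistical toolkit details

* Folded F: larger sample variance in the numerator, two-sided p from
  the F distribution, capped at 1.
* Power of the correlation test: Fisher z normal approximation including
  the (negligible) opposite tail, so power → α as r → 0.
* Fisher's exact test: scipy's two-sided convention (sum of
  hypergeometric probabilities ≤ the observed table's); tests cross-check
  it against exhaustive enumeration.
* t-tests from summary statistics use the pooled-variance form with
  df = n₁ + n₂ − 2, so published group summaries can be re-tested
  without raw data.

## Problem sizes and runtime

The validation experiments use: 50 random centerlines for oracle
equivalence; 100 random 40 × 40 masks plus a 10⁶-pixel uniform field for
the partition checks; one noise-free phantom and 20 noisy phantoms
(80 × 500 × 24 voxels each, one volume per seed) for flow recovery; and
200 simulated cohorts of 31 subjects / 41 eyes for slope recovery and CI
coverage. These sizes put every Monte-Carlo standard error well inside
the tolerance being checked while keeping the full validation run under
a minute.

## Known limitations

* Segmentation has no projection-artifact removal or FAZ handling; it is
  not a replacement for learned segmenters on low-quality scans.
* VTI component definitions follow the invariants stated above; other
  published tortuosity variants (curvature integrals, spline-based
  critical points) will differ in absolute value.
* The LFD uses exactly two box scales, the only faithful choice at
  window 3; it is not a multi-scale fractal estimate.
* Doppler processing assumes pre-computed phase volumes; bulk-motion
  correction, artery/vein classification and phase unwrapping are out of
  scope.
* Mixed-model p-values depend on the df convention in the last digits;
  other software (between-within or Kenward-Roger df) will differ
  slightly at this sample size.
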