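# Methods

## Forward model

The phantom is a 2-D anterior-view torso on a 256×256 grid (row 0 superior,
patient's left = image right; 2.4 mm pixels). Seven binary organ masks —
heart wall (annulus), left-ventricular cavity, mediastinal blood pool,
left/right lung fields, liver, soft-tissue body — carry specific activities
in arbitrary units/pixel. A rendered frame is

    counts ~ Poisson( G_sigma * [ sum_organs A_organ(t) * mask ] * s * T )

with `G_sigma` a Gaussian PSF (default σ = 2 px), `s` the camera
sensitivity (default 2.7 expected counts per activity-unit per minute,
chosen so the cardiac ROI collects ~10⁵ counts on the early scan), and `T`
the acquisition duration (default 10 min). Noise off returns the
expectation image; a fixed seed makes noisy renders bit-reproducible.

### Kinetics

Myocardial activity clears bi-exponentially, mixing the neuronal
(norepinephrine-transporter) and extraneuronal uptake pathways:

    A_heart(t) = A0 [ f_n 2^(−t/112 min) + (1 − f_n) 2^(−t/22 min) ]

(default f_n = 0.85). All other compartments clear mono-exponentially with
one effective blood-pool half-time (default 240 min — a conventional value;
only ratios are anchored to data, absolute scales are simulator
conventions). Physical decay of ¹²³I (T½ = 793.4 min, the standard value)
multiplies everything at render time; truth tables are decay-free, so the
H/M ratio is decay-invariant by construction and the washout formula's
decay factor is exercised non-trivially.

The 112/22-min half-times describe isolated-heart tracer kinetics, not
patient-level retention: a pure-neuronal heart would wash out ~75 % between
15 min and 4 h, whereas heart-failure cohorts average ~34 %. The
washout-recovery generator therefore derives a per-patient *effective*
mono-exponential myocardial half-time from its target washout,
`T_eff = Δt / log2(1/(1 − WR/100))`, keeping the bi-exponential as the
default for uncalibrated kinetics.

### Ideal-background construction

The washout formula treats the mediastinal ROI as the myocardial
background. In the default geometry every non-myocardial compartment shares
the blood-pool clearance, the lung fields are clipped to vertical medial
contours and excluded from an 8-px neighbourhood of the heart disk, and the
LV-cavity activity is scaled once so that the non-myocardial mean in the
(8-px inset) cardiac ROI equals the mediastinal-ROI mean. Because the
matched compartments share one clearance and no foreign activity edge lies
within 4 PSF widths of either ROI boundary, the identity holds at all
times, blurred or unblurred — so background subtraction is exact and the
true washout reduces to the myocardial clearance itself
(`1 − 2^(−Δt/112)` in the pure-neuronal case). Ground truth is defined on
decay-free, unblurred ROI means:

    WR_true = [1 − (S_H(t_l) − S_M(t_l)) / (S_H(t_e) − S_M(t_e))] × 100.

## Quantification conventions

* Pixel (r, c) belongs to a polygon iff its centre (r+0.5, c+0.5) is
  strictly inside under the even-odd rule; rectangles are half-open index
  ranges. These conventions are deterministic and orientation-invariant;
  the rasterizer is verified against an exhaustive point-in-polygon oracle.
* The automatic mediastinal rectangle: lungs are the two largest connected
  low-count regions (< 35 % of the 99th-percentile value, 4-connectivity)
  not touching the image border; top = lung apex, bottom = topmost heart
  polygon row − 1, columns = the medial inter-lung gap at the rectangle's
  mid-height shrunk by a 1-px margin. Counting noise is suppressed before
  thresholding with a σ = 1.5 px Gaussian and a 3-px morphological closing
  of the above-threshold mask (sealing thin noise channels between the
  lungs and the air around the body); the smoothed image is used only for
  landmark detection. The rectangle is placed once per patient series (on
  the first late frame) and propagated, as in clinical reading.
* Washout uses actual (metadata) acquisition times for Δt and the decay
  factor c = 2^(Δt/T½,phys) ≥ 1, which multiplies the background-subtracted
  late counts (Hl − Ml) — c restores the counts lost to physical decay.

## Calibration to H/M targets

`calibrate_to_hm_targets` inverts the full render-and-measure pipeline: for
each target time it solves a bracketed 1-D root-find (Brent) for the
decay-free myocardial specific activity, exploiting strict monotonicity of
the measured ratio in heart activity. Solutions are stored as a tabulated
heart activity curve (log-linear interpolation between knots; a single knot
scales the default bi-exponential shape). A parametric 2-degree-of-freedom
clearance cannot reproduce an arbitrary 4-point H/M pattern to 1e-3, which
is why the calibrated curve is tabulated rather than forced through the
bi-exponential family. When the mediastinal rectangle is auto-placed, the
calibration iterates to a fixed point so the landmarks found on the
calibrated frames reproduce the rectangle the calibration used (residuals
are ~1e-13 in the ratio).

## Statistical pipeline

* **Time model**: random-intercept (compound-symmetry) linear mixed model,
  categorical fixed time effect, REML (statsmodels MixedLM). Patients with
  missing timepoints contribute their available scans. Inference uses the t
  distribution with `n_obs − n_patients − n_time + 1` residual degrees of
  freedom, which reproduces the classical paired analysis in the balanced
  case (the balanced-data contrasts equal within-patient paired-difference
  means to < 1e-8; Satterthwaite approximations are out of scope). Empirical
  95 % CI coverage over 200 simulated cohorts sits in [92 %, 98 %].
* **Margin evaluation**: a contrast is clinically relevant when its
  absolute estimate strictly exceeds the margin (default 0.10); the CI
  check asks whether the 95 % CI contains the margin on the
  absolute-difference scale (negative estimates are reflected first).
* **Exceedance counts**: per late timepoint, the number of patients with
  both scans whose |H/M(t) − H/M(reference)| strictly exceeds the margin;
  absolute differences are used.
* **Power**: exact noncentral-t computation for the paired t-test,
  noncentrality |diff|·√n / SD. The design question ("is the earlier
  acquisition more than the margin away from the standard?") is
  directional, and the one-sided variant is the one consistent with 90 %
  power at n = 49, SD 0.20, diff 0.10, α = 0.0167 (≈ 0.05/3, a
  Bonferroni-style level for three comparisons); sidedness is exposed and
  both variants are unit-tested against a numerical-integration oracle.
* **Group comparisons**: Pearson chi-square *without* continuity correction
  for count tables (the variant consistent with the reference subgroup
  p-value); numeric samples are screened with Shapiro-Wilk at 0.05 and
  routed to the pooled-variance t test or the two-sided Mann-Whitney U
  (verified against full rank-permutation enumeration at small n).

## Cohort generators and study conditions

* Image-level cohorts (`simulate_cohort`): n = 49; log-normal
  between-patient multipliers with CV 0.12 on myocardial and 0.08 on
  blood-pool activity (applied jointly to mediastinum and cavity so the
  ideal-background identity survives); triangular acquisition-time jitter
  with quartiles (13, 15, 19) / (62, 66, 71) / (115, 118, 123) /
  (176, 178, 182) / (236, 239, 245) min for the early/1/2/3/4-h scans; one
  randomly chosen patient misses the 4-h reference scan.
* Measurement-level cohorts (`simulate_hm_cohort`): H/M drawn directly as
  reference mean 1.52 plus fixed time effects (+0.09/+0.05/+0.02 at
  1/2/3 h), patient random intercept SD 0.15, residual SD 0.05 — the
  conditions of the mixed-model recovery and CI-coverage experiments, where
  rendering images would add nothing to what is being tested.
* Washout cohorts (`simulate_washout_cohort`): per-patient true washouts by
  stratified sampling (equal-probability quantiles of N(34, 17²) truncated
  to (2, 80) %, recentred so the mean is exactly 34 %), converted to
  effective myocardial half-times as above.

## Problem sizes and numerics

The recovery and coverage experiments use 200 cohorts of n = 49 each (the
Monte-Carlo standard error of the mean recovered contrast is ~0.0007, an
order of magnitude below the 0.01 scale of interest); the Poisson-render
check uses 500 replicates on a 64×64 phantom, applying the 5σ/√N bound
where ≥ 10 total counts are expected and an exact Poisson tail bound on
dimmer PSF-tail pixels, where the normal approximation is invalid.
Calibration brackets [0, 2^k·A0] and solves to brentq xtol 1e-12; ties and
degenerate inputs (zero-area polygons, empty ROIs, non-increasing
timepoints, infeasible targets below the zero-myocardium baseline) raise
typed, documented errors.

## Limitations

The phantom is a 2-D projection cartoon: no scatter, attenuation,
collimator response beyond a stationary Gaussian PSF, organ motion, or
tomography. Organ outlines are analytic ellipses/disks, so automatic lung
detection is easier than on real anteriors; the landmark rule's robustness
claims transfer to real images only qualitatively. Absolute activity scales
and the blood-pool half-time are conventions; only measured ratios and
their time pattern are calibrated. Passing tests therefore establish the
correctness of the quantification arithmetic, ROI geometry, calibration
inverse, and statistical machinery under the stated study conditions — not
camera physics or patient-level biological variability beyond the modelled
log-normal/jitter/missingness structure. Washout in surrounding lung and
liver tissue can bias real-world washout rates; the ideal-background
construction deliberately removes that influence to make the formula's
correctness testable in isolation.
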