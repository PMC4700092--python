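# mibgkit

Planar cardiac ¹²³I-MIBG semi-quantification and acquisition-time analysis.

¹²³I-metaiodobenzylguanidine (MIBG) scintigraphy images cardiac sympathetic
innervation. The workhorse clinical index is the late **heart-to-mediastinum
ratio (H/M)**: the mean count density (counts/pixel) in a polygonal cardiac
region of interest drawn over the myocardium (left-ventricular cavity
included) divided by the mean count density in a rectangular
upper-mediastinal ROI placed from anatomical landmarks — the lung apex, the
upper cardiac border, and the medial lung contours. Guidelines recommend the
late scan at 4 h post-injection (p.i.); this package implements the full
quantitative chain needed to ask whether scanning earlier (1, 2 or 3 h p.i.)
changes the late H/M ratio by more than a clinically relevant margin of
0.10, in a heart-failure cohort of n = 49.

The package provides:

* **`mibgkit.phantom`** — a synthetic anterior-view planar phantom
  (256×256) with per-organ tracer kinetics (bi-exponential myocardial
  clearance mixing the neuronal pathway, half-time 112 min, with the
  extraneuronal pathway, half-time 22 min; mono-exponential blood-pool
  clearance elsewhere), physical ¹²³I decay (T½ = 793.4 min), Gaussian PSF,
  Poisson counting noise, per-patient variability, acquisition-time jitter,
  and a calibration routine that solves for myocardial activities that make
  the *measured* noiseless H/M hit given targets exactly;
* **`mibgkit.quantify`** — deterministic polygon rasterization
  (pixel-centre, even-odd), mean count densities, landmark-based automatic
  mediastinal ROI placement, the H/M ratio, and the decay- and
  background-corrected washout rate

  `WR = [(He − Me) − (Hl − Ml)·c] / (He − Me) × 100`, `c = 2^(Δt/793.4 min)`;

* **`mibgkit.analysis`** — a random-intercept (compound-symmetry) linear
  mixed model with categorical fixed time effect (REML), contrasts of each
  late timepoint against the 4-h reference with t-based 95 % CIs, the
  0.10-margin evaluation, per-patient exceedance counts, exact
  noncentral-t power of the paired design, and t / Mann-Whitney /
  chi-square subgroup comparisons;
* **`mibgkit.io`** — 16-bit PNG + JSON-sidecar and DICOM image I/O, tidy
  CSV measurement tables, and a seed-reproducible end-to-end pipeline,
  exposed also as the `mibgkit` command line
  (`simulate | quantify | analyze | power | run`).

## Worked example

`python examples/01_phantom_and_hm_ratio.py` calibrates the phantom to the
group-mean late H/M values and re-measures them through the full
render → ROI → ratio pipeline:

```
time p.i.   H (cts/px)   M (cts/px)   H/M   target
     60 min      40.41        25.25   1.600    1.60
    120 min      31.43        20.15   1.560    1.56
    180 min      24.59        16.07   1.530    1.53
    240 min      19.49        12.82   1.520    1.52
```

H and M are mean count densities in the cardiac and mediastinal ROIs; their
ratio declines from 1.60 at 1 h to 1.52 at 4 h — a mean drift of 0.08,
below the 0.10 clinical-relevance margin. `examples/03_...py` fits the
mixed model on a simulated n = 49 cohort and prints the contrasts vs 4 h
with CIs, the margin verdict, and the per-patient exceedance counts;
`examples/02_...py` recovers known washout rates from noisy frames;
`examples/04_...py` reproduces the paired-design power:

```
paired t-test power at n=49, SD 0.20, diff 0.10, alpha 0.0167: 0.901
```

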