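"""Washout-rate quantification against known ground truth.

Simulates a small cohort whose true 4-h washouts average exactly 34 %, then
recovers the washout from noisy rendered images using the decay- and
background-corrected formula

    WR = [(He - Me) - (Hl - Ml) * c] / (He - Me) * 100,
    c  = 2**(dt / 793.4 min)
"""

import numpy as np

from mibgkit import (
    default_phantom,
    ideal_background_rois,
    measure_scan,
    simulate_washout_cohort,
    washout_rate,
)

geometry, kinetics = default_phantom()
patients, truth = simulate_washout_cohort(
    n=12, mean_wr=34.0, sd_wr=17.0, geometry=geometry, kinetics=kinetics, seed=42
)
rois = ideal_background_rois(geometry)

print("patient   true WR (%)   measured WR (%)")
measured = []
for series, wr_true in zip(patients, truth.wr_true):
    early = measure_scan(series.frames[0], rois)
    late = measure_scan(series.frames[1], rois)
    wr = washout_rate(early, late)
    measured.append(wr.wr_percent)
    print(f"{series.patient_id}   {wr_true:9.1f} {wr.wr_percent:15.1f}")

print(f"\ncohort mean: true {truth.wr_true.mean():.1f} %, "
      f"measured {np.mean(measured):.1f} % (Poisson noise, n={len(patients)})")
# Per-patient values scatter with counting noise, but the cohort mean tracks
# the generating truth closely because background subtraction is exact on
# the ideal-background phantom and the decay factor c restores the counts
# lost to physical decay of the tracer.
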