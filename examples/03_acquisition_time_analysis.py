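"""Repeated-measures analysis of acquisition time vs the 4-h reference.

Generates a measurement-level cohort (n=49, one patient missing the
reference scan) with time effects +0.09/+0.05/+0.02 at 1/2/3 h, fits the
random-intercept mixed model, and evaluates the 0.10 clinical-relevance
margin and the per-patient exceedance counts.
"""

from mibgkit import (
    evaluate_margin,
    exceedance_counts,
    fit_time_model,
    simulate_hm_cohort,
)

table = simulate_hm_cohort(n=49, seed=20151029)
result = fit_time_model(table, reference="4h")

print("contrast vs 4 h (estimate [95 % CI], p):")
for lab, row in result.contrasts.iterrows():
    print(
        f"  {lab}: {row.estimate:+.3f} [{row.ci_low:+.3f}, {row.ci_high:+.3f}], "
        f"p = {row.p:.2g}"
    )

margin = evaluate_margin(result, margin=0.10)
print(f"\nmargin evaluation: {margin.verdict}")

exceed = exceedance_counts(table, reference="4h", margin=0.10)
print("\nper-patient |difference| > 0.10:")
for lab, row in exceed.iterrows():
    print(f"  {lab}: {int(row.n_exceeding)}/{int(row.n_pairs)} patients ({row.percent:.0f} %)")

# The generating 1-h effect is +0.09, i.e. below the margin; in any single
# cohort the estimate scatters around it (here a draw just above 0.10), which
# is exactly why the margin is judged against the estimate AND its CI rather
# than a point value, and why half the individual patients can move by more
# than 0.10 at 1 h even when the mean difference does not.
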