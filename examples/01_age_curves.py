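"""Developmental age curves: generate a normative cohort and recover APRs.

Builds a synthetic multi-site healthy adolescent cohort (n=1200, ages
8-22), TICV-corrects the regional volumes, applies the ±3 SD QC capping
and fits the per-region OLS age curve.  The annual percent rate (APR)
printed per region should recover the calibrated trajectory: grey
matter regions decline (posterior cingulate ~ -1.9 %/yr), white matter
tracts rise (corticospinal tract ~ +0.8 %/yr).
"""

import normvol as nv

cfg = nv.GeneratorConfig(n_subjects=1200, seed=0)
cohort = nv.generate_normative_cohort(cfg)
capped, removed = nv.cap_outliers(nv.correct_table(cohort))
print(f"cohort: {len(cohort)} subjects, QC removed {len(removed)} cell values\n")

print(f"{'region':24s} {'APR %/yr':>9s} {'change 8->20 %':>15s}")
for region in nv.region_columns(cohort):
    curve = nv.fit_age_curve(capped, region)
    change = nv.percent_change_between(curve, 8, 20)
    print(f"{region:24s} {curve.apr:+9.2f} {change:+15.1f}")

print(
    "\nAPR is the fitted per-year percent change of the TICV-corrected "
    "volume relative to its age-8 value; the 8->20 change is 12x APR "
    "under the linear model (global grey ~ -17%, global white ~ +9%)."
)
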