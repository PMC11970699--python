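"""Estimate the 1971 refugee death toll from the bundled camp records.

Loads the seventeen camp records, reduces each to person-time exposures,
fits the baseline and monsoon-excess death rates by robust regression,
projects them onto the whole refugee population's person-time, and
composes the excess-toll confidence interval.
"""

import campmort as cm

result = cm.run_pipeline("bundled")
r, t = result.rates, result.tolls

print("Fitted death rates (deaths per million person-days):")
print(f"  baseline b       = {r.b:8.2f}")
print(f"  monsoon excess m = {r.m:8.2f}")
print()
print("Projected death tolls (deaths):")
print(f"  baseline  = {t.baseline_toll:12,.1f}   (b x 1853.65 M person-days)")
print(f"  monsoon   = {t.monsoon_toll:12,.1f}   (m x  884.06 M person-days)")
print(f"  total     = {t.total_toll:12,.1f}")
print(f"  natural   = {t.natural_toll:12,.1f}   (peacetime CDR 17/1000/yr)")
print(f"  excess    = {t.excess_toll:12,.1f}   (total - natural)")
print()
lo, hi = t.excess_ci
print(f"Excess-toll 95% CI: ({lo:,.0f}, {hi:,.0f})")
print()
print("The excess toll is the number of deaths attributable to camp")
print("conditions beyond what peacetime mortality would have caused over")
print("the same person-time. The interval combines binomial count noise")
print("with leave-one-out source-data variability, inflated 1.545x for")
print("age-stratified mortality heterogeneity.")
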