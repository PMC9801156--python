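"""Applied-water accounting from the packaged field-trial tables.

Sums the April-September irrigation volumes of the three subsurface-drip
treatments (125/100/75% of crop water requirement), converts the deficit
treatment's total to a depth, and compares yields and water productivity.
"""

from acvoanfis import (
    applied_water_ledger,
    depth_mm,
    seasonal_applied_water,
    treatment_comparison,
    treatment_summaries,
)

ledger = applied_water_ledger()
for t in ("T1", "T2", "T3"):
    v = seasonal_applied_water(ledger, t)
    print(f"{t}: {v:9.2f} m3/ha  ({depth_mm(v):7.2f} mm)")
# T3's seasonal irrigation water and the volume it saves against the
# 125% and 100% treatments:
t1, t2, t3 = (seasonal_applied_water(ledger, t) for t in ("T1", "T2", "T3"))
print(f"T3 saves {t1 - t3:.2f} m3/ha vs T1 and {t2 - t3:.2f} m3/ha vs T2")

# Yield advantage (%) and water-productivity edge of the deficit treatment:
for c in treatment_comparison(treatment_summaries(), "T3"):
    print(f"T3 vs {c.treatment}: yield +{c.yield_advantage_pct:.2f}%, "
          f"WP +{c.wp_difference:.3f} kg/m3")
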