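"""Per-species strike energetics for a standard 20 m canopy tree.

Builds the same 20 m stem (27.3 cm base, 1 cm top, 1 cm cylinders) under
each packaged species' resistivity function and prints total series
resistance, heating under a single 30 kA return stroke, and maximum
power.  More resistive species absorb proportionally more of both.
"""

import treestrike as ts

table = ts.species_table()
print(f"{'species':24s} {'R (kOhm)':>9s} {'H_D1 (GJ)':>10s} {'P (TW)':>8s}")
for _, row in table.sort_values("resistance_kohm").iterrows():
    print(
        f"{row['name']:24s} {row['resistance_kohm']:9.0f} "
        f"{row['heating_d1_gj']:10.1f} {row['max_power_tw']:8.0f}"
    )
print(
    "\nHeating = action integral x resistance; power = peak current^2 x "
    "resistance,\nso species differences in resistance map directly onto "
    "energy absorbed."
)
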