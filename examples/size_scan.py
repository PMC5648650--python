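"""How tree size changes strike severity.

Taller, thicker trees absorb more total energy but spread it over far
more tissue, so heating density (the damage proxy) collapses with size.
"""

import treestrike as ts

table = ts.size_scan_table()
for species, group in table.groupby("species", sort=False):
    print(f"\n{species}")
    print(f"  {'height':>6s} {'R (kOhm)':>9s} {'V (m3)':>7s} {'H (GJ)':>7s} {'HD (kJ/cm3)':>12s}")
    for _, r in group.iterrows():
        print(
            f"  {r['height_m']:6.0f} {r['resistance_kohm']:9.0f} {r['volume_m3']:7.2f} "
            f"{r['heating_gj']:7.1f} {r['heat_density_kj_cm3']:12.1f}"
        )
small = table.set_index(["species", "height_m"])
ratio = (
    small.loc[("Alseis blackiana", 10), "heat_density_kj_cm3"]
    / small.loc[("Dipteryx panamensis", 30), "heat_density_kj_cm3"]
)
print(
    f"\nA 10 m Alseis concentrates ~{ratio:.0f}x the heating density of a "
    "30 m Dipteryx:\nsmall, narrow trees are the ones a strike destroys."
)
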