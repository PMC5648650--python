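"""Lianas as natural lightning rods.

A liana climbing a tree is a parallel conductor at the same potential,
so it steals current in proportion to its conductance.  Heating and
power in the tree both fall by the square of the tree's current
fraction.
"""

import treestrike as ts

constants = ts.default_constants()
calibration = ts.calibrate_liana_resistances()
print("calibrated liana resistance (25 m stem):",
      {k: f"{v/1e6:.2f} MOhm" for k, v in calibration.items()})

jac = ts.get_species_model("Jacaranda copaia")
for n in (0, 1, 3):
    rep = ts.strike_complex(
        ts.build_complex(jac, n_lianas=n), constants, liana_calibration=calibration
    )
    print(
        f"{n} liana(s): tree carries {rep.tree.current_fraction:5.1%} of current, "
        f"heating {rep.tree.heating/1e9:5.2f} GJ, diverted {rep.percent_diverted:4.1f}%"
    )

models = list(ts.species_models().values())
for n in (1, 3):
    s = ts.protection_summary(models, constants, n_lianas=n,
                              liana_calibration=calibration)
    print(f"across 11 species, {n} liana(s): {s.mean_percent:.1f} +/- {s.sd_percent:.1f}% diverted")
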