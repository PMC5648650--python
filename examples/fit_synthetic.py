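"""Round-tripping the fitting utilities on synthetic field data.

Generates a measurement campaign with known resistivity-diameter and
moisture effects, refits both models, and prints recovered vs true
coefficients.
"""

import treestrike as ts

cfg = ts.FixtureConfig(n=200, noise_sd=0.4, seed=7)
fit = ts.fit_resistivity_model(ts.generate_resistivity_measurements(cfg))
print("resistivity-diameter fit:")
print(f"  slope     {fit.model.slope:6.2f}  (true {cfg.model.slope}, SE {fit.slope_se:.2f})")
print(f"  intercept {fit.model.intercept:6.2f}  (true {cfg.model.intercept}, SE {fit.intercept_se:.2f})")
print(f"  R^2 {fit.r_squared:.3f} on n={fit.n}")

mfit = ts.fit_moisture_model(ts.generate_moisture_measurements(cfg))
print("moisture fit:")
print(f"  slope {mfit.slope:6.2f} ln(Ohm m) per moisture fraction "
      f"(true {-cfg.moisture_slope}), R^2 {mfit.r_squared:.3f}")
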