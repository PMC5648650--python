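# Methods

## Model overview

`treestrike` treats a lightning strike as a purely resistive heating
event in a network of one or more woody conductors. Three layers feed
the calculation:

1. **Resistivity** -- species-level functions `ln p = m·d^(1/3) + b`
   (`d` in metres, `p` in ohm·m) mapping stem diameter to tissue
   resistivity. The cube-root/log transform pair linearises the strong
   rise of resistivity with diameter seen in field data.
2. **Geometry** -- a stem is a linearly tapering cone discretised into
   short cylinders; resistivity evaluated per cylinder gives a series
   resistance and a volume.
3. **Energetics** -- a discharge is summarised by its action integral
   `AI = ∫i²dt` and peak current `Ipk`; heating is `AI·R`, maximum power
   `Ipk²·R`, heating density `H/V`. Lianas are parallel conductors under
   a common potential; the current divider and the quadratic dependence
   of heating on current give the protection factor `f²` with
   `f = R_liana/(R_tree + R_liana)`.

Assumptions inherited by everything downstream: current flows
longitudinally through the stem; tissue resistivity does not change
during the discharge; heat is deposited uniformly over stem volume with
no losses or flashover; a resistance measured with an ohmmeter is the
resistance lightning current encounters. Temperature at measurement time
is carried as metadata only and never enters a computation.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| top (minimum) diameter | 0.01 | m | fixed crown-tip diameter of every model stem |
| segment length | 0.01 | m | discretisation; results stable to <1% under doubling |
| reference tree | 20 m, 0.273 m basal | m | standard geometry for interspecific comparison |
| liana basal diameter | 0.06 | m | conservative maximum for a canopy liana |
| liana length | 1.25 x host height | m | sinuous, scandent growth habit |
| CC segment | 200 A, 0.115 s | A, s | canonical continuing-current flash |
| first-stroke peak | 30 | kA | canonical return-stroke peak current |

## Cylinder diameter convention

The taper assigns each cylinder the diameter of the cone at its **top
face**, so the per-segment decrement is `(d_base − d_top)/n` with
`n = round(length/segment_length)` and the topmost cylinder has exactly
the fixed 1 cm minimum diameter. Midpoint and bottom-face conventions
are available via `build_tapered_stem(..., convention=...)`; the three
agree to well under 1% at 1 cm segments. The top-face convention is the
default because it honours the fixed crown-tip diameter exactly and
reproduces the published reference volumes at their printed precision.
Non-integer length/segment ratios fold the remainder into the final
segment's length.

The discretised volume converges on the frustum closed form
`(πL/3)(r_b² + r_b·r_t + r_t²)`; at 1 cm segments agreement is within
0.5% for all tree-scale geometries in the package.

## Discharge constants: calibration vs waveform

The energetics layer uses `CalibratedDischargeConstants`, obtained by
inverting `H = AI·R` and `P = Ipk²·R` against the packaged per-species
reference table: heating/resistance and sqrt(power/resistance) are
species-independent to ~0.5% and ~0.04% respectively (the residual
spread is the table's three-significant-figure rounding), and averaging
over species gives

    AI_D1 = 1.482e4 A²·s   AI_D2 = 2.169e4 A²·s   AI_D3 = 1.941e4 A²·s
    effective peak = 3.009e4 A

`AI_D3 − AI_D1 = 4,588 A²·s`, matching the closed-form continuing-current
contribution `200² x 0.115 = 4,600 A²·s` to 0.3%.

The packaged Heidler configuration exists so profiles can be inspected
and varied. Its first stroke (τ₁ = 1.8 µs, n = 2) has its amplitude set
for a 30 kA peak and its decay constant (τ₂ = 22.61 µs) set so the
full-waveform action integral equals the calibrated `AI_D1`; the 12 kA
subsequent strokes (τ₁ = 0.25 µs, τ₂ = 43.37 µs) each contribute half of
`AI_D2 − AI_D1`. Truncating the first stroke at 50 µs for the
continuing-current flash sheds ~1.6% of its action integral, so the
waveform route agrees with the calibrated constants within 1.2% on D3
and exactly on D1/D2. Inter-stroke spacing is 40 ms; any non-overlapping
value gives identical action integrals. Integration is fixed-step
trapezoid at 10 ns over each stroke's support (refining to 1 ns moves
the result by <1e-4 relative); constant-current segments use the closed
form `I²·t`.

## Liana resistances

No liana resistivity-diameter function is packaged, so default liana
conductors carry a calibrated total resistance per region. Calibration
inverts the published one-liana heating reductions: `f = sqrt(H_1L/H_0L)`
per species, `R_l = R_t·f/(1 − f)` with `R_t` the package's own computed
20 m tree resistance, averaged within region:

    tropical  ~2.98 MOhm    temperate ~3.98 MOhm    (25 m reference stem)

Resistance scales linearly with stem length at fixed taper, as for any
fixed-profile series conductor. Multiple lianas are identical copies
combined in parallel; a user-supplied `resistance_override` (or a liana
resistivity model run through the geometry layer) takes precedence.

## Synthetic measurement generator

`FixtureConfig` emulates a field campaign: diameters uniform over
1-10 cm, log-scale Gaussian residuals (SD 0.4 by default, typical of
field scatter), electrode span 30 cm, and a moisture model
`ln p = a − c·w` with `a = 8`, `c = 6` over moisture fractions 0.30-0.60
(resistivity falls with moisture; the defaults put resistivities in the
hundreds of ohm·m, the observed range for small stems). The generator
reproduces exactly the statistical structure the fitters assume, so
passing recovery tests demonstrates correctness of the fitting code, not
robustness to heteroscedasticity, size-stratified sampling, repeated
measures, or phylogenetic structure, none of which are emulated.

## Numerical and degenerate-input choices

* Diameters are clipped into `[d_top, d_base]` after the taper is
  evaluated, guarding the endpoints against floating-point drift.
* Fits require ≥3 points and a non-degenerate design matrix
  (`InsufficientDataError` otherwise); OLS is plain, unweighted
  (statsmodels), with R², residual SD, and coefficient SEs reported.
* `tree_current_fraction` is open-interval: zero or negative resistances
  are rejected rather than saturated.
* Percentages are kept at full precision internally; rounding to the
  printed integer happens only at reporting boundaries.

## Known limitations

* One known data defect: the packaged Pinus virginiana regression
  coefficients reconstruct a reference resistance ~2% above the
  published value (back-solving implies slope 9.04 vs the printed 9.09),
  while all other ten species reproduce within 0.8%. The printed
  coefficients are kept as-is.
* No branching architecture, crown shape, or non-linear taper; no
  strike-probability model; no temperature rise or tissue-damage
  thresholds; no flashover between conductors. Heating density is a
  proxy, not a physiological damage prediction.
* The liana resistance calibration is only as good as the published
  reductions it inverts; it refers to a 6 cm basal, 25 m liana and
  scales linearly in length only.
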