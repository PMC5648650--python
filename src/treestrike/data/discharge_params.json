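{
  "comment": "Default stroke parameters for the three canonical discharges. The first (return) stroke carries the canonical 30 kA peak; its decay constant is set so that the full-waveform action integral equals the value implied by the published heating/resistance pairs (~1.48e4 A^2 s). Subsequent strokes are smaller (12 kA peak) with their decay set so each contributes the published multi-stroke increment.",
  "first_stroke": {
    "terms": [
      {"amplitude_a": 28364.0, "eta": 0.67098, "tau1_s": 1.8e-06, "tau2_s": 2.261e-05, "exponent": 2}
    ],
    "duration_s": 0.002
  },
  "subsequent_stroke": {
    "terms": [
      {"amplitude_a": 11451.0, "eta": 0.89819, "tau1_s": 2.5e-07, "tau2_s": 4.337e-05, "exponent": 2}
    ],
    "duration_s": 0.002
  },
  "interstroke_offset_s": 0.04,
  "d3_stroke_truncation_s": 5e-05,
  "cc_amplitude_a": 200.0,
  "cc_duration_s": 0.115
}
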