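{
  "tissue": "cartilage",
  "description": "Published fit for articular cartilage: b1 from confined compression at equilibrium, b2/b3 from multistep tensile equilibria, b4 and the spectrum from 5-step 2% ramp-relaxation tension at 0.15 %/s. SI units: Pa, Pa.s, s.",
  "b1": 42500.0,
  "b2": 50000.0,
  "b3": 14200000.0,
  "b4": 190000000.0,
  "spectrum": {
    "tau_s": [141.0, 3.55, 14303.43],
    "w": [0.346, 0.0709, 0.582]
  }
}
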