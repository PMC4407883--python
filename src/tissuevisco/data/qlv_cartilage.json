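{
  "description": "Literature quasi-linear viscoelastic (QLV) reduced-relaxation parameters used for the model-contrast simulations: g_i are short-term/equilibrium stress ratios, tau_i time constants.",
  "g": [0.87, 0.036, 0.273],
  "tau_s": [10.0, 100.0, 1000.0]
}
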