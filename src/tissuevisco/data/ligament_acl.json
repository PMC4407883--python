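{
  "tissue": "ligament",
  "description": "Published fit for anterior cruciate ligament uniaxial tension (near-equilibrium 1.2 %/s elastic stage; 25 %/s short-term viscous stage; stress-relaxation spectrum). SI units: Pa, Pa.s, s.",
  "a1": 0.0,
  "a2": 2213000.0,
  "a3": 3.879,
  "a4": 365300.0,
  "a5": 0.652,
  "spectrum": {
    "tau_s": [3.77, 148.24, 10987.98],
    "w": [0.154, 0.161, 0.682]
  }
}
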