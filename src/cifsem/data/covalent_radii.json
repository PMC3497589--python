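{
  "H": 0.31,
  "B": 0.84,
  "C": 0.76,
  "N": 0.71,
  "O": 0.66,
  "F": 0.57,
  "P": 1.07,
  "S": 1.05,
  "Cl": 1.02,
  "Br": 1.20,
  "I": 1.39
}
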