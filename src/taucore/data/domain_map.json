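{
  "template_length": 441,
  "intervals": {
    "N_head": [1, 44],
    "N1_insert": [45, 73],
    "N2_insert": [74, 102],
    "mid": [103, 150],
    "proline_rich": [151, 243],
    "R1": [244, 274],
    "R2": [275, 305],
    "R3": [306, 336],
    "R4": [337, 368],
    "C_tail": [369, 441]
  }
}
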