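{
  "CO2": [{"subfamily": "PIP"}],
  "Si": [{"subfamily": "NIP", "arR": "GSGR"}],
  "As": [{"subfamily": "NIP"}],
  "Sb": [{"subfamily": "NIP"}],
  "NH3": [{"subfamily": "TIP"}],
  "Bo": [{"subfamily": "NIP", "group": 5}, {"subfamily": "XIP"}],
  "U": [{"subfamily": "TIP"}, {"subfamily": "XIP"}]
}
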