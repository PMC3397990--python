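# Stand-in 7-gene benchmark topology: 10 edges, 35 free kinetic parameters.
# Invented connected wiring, not a published topology.
genes: ["1", "2", "3", "4", "5", "6", "7"]
interactions:
  - {from: "1", to: "2", sign: activation}
  - {from: "2", to: "3", sign: activation}
  - {from: "3", to: "1", sign: repression}
  - {from: "2", to: "4", sign: repression}
  - {from: "4", to: "5", sign: activation}
  - {from: "5", to: "6", sign: repression}
  - {from: "6", to: "7", sign: activation}
  - {from: "7", to: "4", sign: repression}
  - {from: "1", to: "6", sign: activation}
  - {from: "3", to: "7", sign: activation}
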