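# Stand-in 9-gene benchmark topology: 15 edges, 49 free kinetic parameters.
# Invented connected wiring, not a published topology.
genes: ["1", "2", "3", "4", "5", "6", "7", "8", "9"]
interactions:
  - {from: "1", to: "2", sign: activation}
  - {from: "2", to: "3", sign: repression}
  - {from: "3", to: "4", sign: activation}
  - {from: "4", to: "1", sign: repression}
  - {from: "2", to: "5", sign: activation}
  - {from: "5", to: "6", sign: activation}
  - {from: "6", to: "2", sign: repression}
  - {from: "5", to: "7", sign: repression}
  - {from: "7", to: "8", sign: activation}
  - {from: "8", to: "9", sign: activation}
  - {from: "9", to: "7", sign: repression}
  - {from: "1", to: "8", sign: repression}
  - {from: "3", to: "9", sign: activation}
  - {from: "6", to: "9", sign: repression}
  - {from: "4", to: "6", sign: activation}
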