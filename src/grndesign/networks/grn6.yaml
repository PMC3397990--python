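# Stand-in 6-gene benchmark topology: 8 signed Hill-regulated edges,
# 29 free kinetic parameters. The wiring is an invented connected network
# with one negative feedback loop; it is not a published topology.
genes: ["1", "2", "3", "4", "5", "6"]
interactions:
  - {from: "1", to: "2", sign: activation}
  - {from: "1", to: "3", sign: repression}
  - {from: "2", to: "4", sign: activation}
  - {from: "3", to: "4", sign: repression}
  - {from: "4", to: "5", sign: activation}
  - {from: "5", to: "6", sign: activation}
  - {from: "6", to: "1", sign: repression}
  - {from: "2", to: "6", sign: activation}
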