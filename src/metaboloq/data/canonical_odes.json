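{
  "_comment": "Reference term multisets of the canonical ODE system, one signed reaction term per entry, transcribed independently of the network builder. Used by `metaboloq compile --check` and the equation-fidelity tests.",
  "x1": [["-", "r1"], ["-", "r3"], ["+", "r6"], ["+", "r7"]],
  "x2": [["-", "r1"], ["-", "r3"]],
  "x3": [["-", "r1"], ["-", "r2"], ["-", "r3"], ["-", "r4"], ["-", "r5"], ["-", "r6"], ["-", "r7"]],
  "x4": [["+", "r1"], ["-", "r2"], ["+", "r3"], ["-", "r4"]],
  "x5": [["+", "r1"], ["+", "r3"]],
  "x6": [["+", "r1"], ["+", "r2"], ["+", "r3"], ["+", "r4"]],
  "x7": [["+", "r6"], ["+", "r7"]],
  "x8": [["-", "r2"], ["-", "r4"], ["+", "r5"], ["+", "r6"]],
  "x9": [["-", "r5"]],
  "x10": [["+", "r5"], ["-", "r6"]],
  "x11": [["+", "r6"]],
  "x12": [["+", "r2"], ["-", "r5"], ["-", "r7"]],
  "x13": [["+", "r4"], ["-", "r6"], ["-", "r7"]],
  "x14": [["+", "r5"], ["-", "r6"]]
}
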