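{
  "comment": "RNA/RNA Watson-Crick nearest-neighbor stack free energies at 37C, kcal/mol. Key is the 5'->3' dinucleotide on the strand carrying the step; the paired strand is its Watson-Crick complement. duplex_initiation is added once per duplex.",
  "duplex_initiation": 4.1,
  "stacks": {
    "AA": -0.93,
    "AU": -1.10,
    "AC": -2.24,
    "AG": -2.08,
    "UA": -1.33,
    "UU": -0.93,
    "UG": -2.11,
    "UC": -2.35,
    "CA": -2.11,
    "CU": -2.08,
    "CC": -3.26,
    "CG": -2.36,
    "GA": -2.35,
    "GU": -2.24,
    "GG": -3.26,
    "GC": -3.42
  }
}
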