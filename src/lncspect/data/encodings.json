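{
  "version": "1",
  "comment": "Per-base numeric encoding tables for genomic signal processing. Complex values are [re, im] pairs. These constants follow the conventions of the MathFeature descriptor suite.",
  "eiip": {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335},
  "atomic": {"A": 70, "C": 58, "G": 78, "T": 66},
  "complex": {"A": [1, 1], "C": [-1, -1], "G": [-1, 1], "T": [1, -1]},
  "real": {"T": 1.5, "C": 0.5, "G": -0.5, "A": -1.5},
  "integer": {"T": 0, "C": 1, "A": 2, "G": 3}
}
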