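{
  "alignment_columns": 120,
  "focal_group": "F1",
  "mode_counts": {
    "ambiguous": 2,
    "intergenic": 19,
    "intragenic": 0
  },
  "motif_fisher_p": 1.0,
  "motif_table": [
    [
      2,
      12
    ],
    [
      0,
      2
    ]
  ],
  "n_fusion_loci": 1,
  "n_groups": {
    "F": 1,
    "R": 1
  },
  "n_loci": 16,
  "n_subgroups": 0,
  "n_units_detected": 28,
  "n_units_nonredundant": 21
}
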