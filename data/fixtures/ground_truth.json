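{
  "alignments": {
    "homogeneous": 11,
    "saturated": 13,
    "shifted": 12
  },
  "gene_trees": {
    "config": {
      "gene_count": 21,
      "length_noise_sigma": 0.25,
      "nni_moves": 0.3,
      "outlier_count": 1,
      "seed": 1101,
      "taxon_count": 16
    },
    "outlier_indices": [
      8
    ],
    "outlier_names": [
      "gene_008"
    ]
  },
  "paired_3x": {
    "noise_multiplier_b": 3.0,
    "seed": 1103
  },
  "paired_null": {
    "noise_multiplier_b": 1.0,
    "seed": 1102
  }
}
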