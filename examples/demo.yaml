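# Demo pipeline config: a clean single-group iPSC cohort with a positive
# control carrying 1.5x dosage gains on chromosomes 2 and 5 in sample iPSC_1.
simulate:
  n_chromosomes: 6
  genes_per_chromosome: 500
  n_samples_per_group: 6
  group_labels: [iPSC]
  de_fraction: 0.0
  aneuploidies:
    - {sample: iPSC_1, chromosome: chr2, dosage: 1.5}
    - {sample: iPSC_1, chromosome: chr5, dosage: 1.5}
seed: 11
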