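# Demo workflow: a small two-condition synthetic dataset run end to end.
seed: 7
conditions: [meiosis, mitosis]
simulate:
  n_chromosomes: 1
  chrom_length: 60000
  gc_content: 0.36
  n_genes: 15
  gene_length_mean: 1200
  coverage: 40
  toggled_ndr_fraction: 0.2
wavelet: bior3.5
level: 5
shift_window: [100, 250]
min_height: 1.0
min_separation: 100
ndr_min_length: 150
ndr_max_occupancy: 0.4
min_overlap_fraction: 0.5
anchor: "+1N"
flank: 800
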