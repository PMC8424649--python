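# Default configuration for the packaged biallelic (20 / 118 repeat)
# cell-line-like fixture: three genotypes differing only in their per-day
# expansion probability, three replicates each, sampled over six weeks.
locus: HTT
founder_repeats: [20, 118]
n_cells: 2000
days: [0, 14, 28, 42]
# Alleles shorter than this many repeats are treated as stable (the short
# endogenous allele does not measurably expand on this time scale).
min_unstable_repeat: 30
replicates: 3
genotypes:
  FL_like:       {p_expand: 0.03, p_contract: 0.0}  # slow expander
  KO_like:       {p_expand: 0.15, p_contract: 0.0}  # fast expander
  MMRnull_like:  {p_expand: 0.0,  p_contract: 0.0}  # non-expander
render:
  stutter_ratio: 0.15
  stutter_steps: 3
  size_noise_sd: 0.25
  height_noise_cv: 0.05
  repeat_unit_bp: 3
  flank_bp: 100.0
calibration:
  reference_repeat: 20
  reference_size_bp: 160.0
  repeat_unit_bp: 3
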