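# Shared run configuration for the numbered analysis drivers.
# The panel is a desk-scale analog of the study design: one wild group plus
# three regional landrace subpopulations, differentiated at the published
# pairwise Fst levels, with mean read depth 13.
seed: 20210905
outdir: results
# the >=20 homozygous-minor post-filter is calibrated for ~2000 samples;
# scale it to this 600-sample panel
min_homozygous_minor: 6
simulate:
  n_per_group: {WILD: 60, NR: 140, HR: 140, SR: 260}
  n_snps: 4000
  n_chromosomes: 20
  chrom_length_bp: 40000000
  n_causal: 12
  h2_target: 0.66
  depth_mean: 13.0
  missing_rate: 0.05
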