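# Four genotype presets compared against the wild type: symmetric recycling
# (WT), leading-biased (mcm2-2A-like), lagging-biased (dpb4d-like) and
# recycling-impaired double mutant. Presets are qualitative phenotype classes,
# not fitted parameter estimates.
seed: 7
outdir: espan_run
simulation:
  n_origins: 200
  genotypes: [WT, mcm2-2A, dpb4d, mcm2-2A_dpb4d]
  marks: [H3K4me3, H3K56ac]
analysis:
  reference: WT
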