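# Single-region synthetic study driving the numbered analysis scripts.
# One brain region, 4 treatment groups x 12 mice, 2,000 probesets with five
# planted 100-gene coexpression modules: module 1 linked to cycle-4 drinking
# change (target Spearman rho 0.7), module 2 connectivity-disrupted in the
# CIE Drinking group, 100 background genes shifted in CIE Drinking.
seed: 11
universe: all   # planted modules carry no group-mean signal, so the ANOVA
                # universe would strip them; the filter is exercised in 02
simulate:
  n_genes: 2000
  module_sizes: [100, 100, 100, 100, 100]
  n_per_group: 12
  loading_range: [0.5, 0.9]
  noise_sd: 0.5
  n_de_genes: 100
  de_effect: 0.8
  trait_linked_modules: {0: 0.7}
  disrupted_modules: {1: ["CIE Drinking", 0.8]}
  seed: 11
network:
  power: 6
  deep_split: 2
  min_module_size: 30
validate_n_perm: 100
disrupt_n_boot: 200
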