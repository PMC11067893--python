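# Scaled demo: 12 taxa, 6 partitions, full pipeline including the SH test.
# Run with:  mitoconcord run -c configs/demo.yaml
seed: 2024
output_dir: results/demo
simulate:
  n_taxa: 12
  tree_height_scale: 0.6
  min_branch_length: 0.02
  partitions:
    g150: 150
    g300: 300
    g450: 450
    g600: 600
    g750: 750
    g900: 900
  model:
    exchangeabilities: [1, 3, 1, 1, 3, 1]
    base_freqs: [0.32, 0.28, 0.15, 0.25]
    gamma_shape: 0.7
    n_categories: 4
model:
  exchangeabilities: [1, 3, 1, 1, 3, 1]
  base_freqs: [0.32, 0.28, 0.15, 0.25]
  gamma_shape: 0.7
  n_categories: 4
sh_test:
  enabled: true
  n_replicates: 1000
scf:
  n_quartets: 100
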