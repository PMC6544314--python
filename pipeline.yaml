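# Desk-scale example configuration for `social-interactome run`.
# Full-scale analyses raise n_perm/n_trees/n_runs/k to 1000.
out_dir: socint_out
sim:
  n_genes_per_tissue: 150
  seed: 0
alpha: 0.05
k: 60
min_mean: 1.0
min_stages: 1
pseudocount: 1.0
n_perm: 200
n_trees: 50
n_runs: 3
n_boot: 500
seed: 0
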