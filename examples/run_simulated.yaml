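# End-to-end run on a simulated dual-platform dataset.
# Usage: xplatclust run-all --config examples/run_simulated.yaml
outdir: scratch/example_run
seed: 11
sim:
  n_clusters: 8
  genes_per_cluster: 50
  replication_fraction: 0.8
  amplitude_range: [1.5, 3.0]
  profile_noise_sd: 0.15
  nb_dispersion: 0.05
  n_enriched_classes: 2
  enrichment_factor: 4.0
k_rule: "fixed:8"
n_init: 25
n_randomizations: 5
pcc_threshold: 0.5
fc_threshold: 1.0
frac_threshold: 0.5
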