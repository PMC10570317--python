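# Example configuration for `stressgcn run --config example_config.yaml`.
# Defaults shown; paths are relative to the working directory.
counts: data/counts.tsv
samples: data/samples.tsv
annotation: data/annotation.tsv
out_dir: stressgcn_out

# DEG calling (per condition/time point versus matched mock)
log2fc_cutoff: 1.0
fdr_cutoff: 0.05

# co-expression networks
r_threshold: 0.9
correlation_mode: signed      # or: absolute
block_size: 2000

# integration: merge these conditions into named networks; omit to merge
# every condition into one network called "integrated"
network_groups:
  abiotic: [stress1, stress2]
  biotic: [stress3]
shared_only: 1                # keep nodes present in >= m input networks
hub_metric: degree            # or: betweenness

# core reconstruction / enrichment
go_filter: ["GO:0050896"]
enrichment_method: hypergeometric   # or: length_weighted

# expression profiling
n_clusters:
  abiotic: 5
  biotic: 8
cluster_method: hierarchical_ward   # or: kmeans

pca_components: 2
seed: 0
log_level: INFO
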