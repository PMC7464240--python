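# Replication settings for the psoriasis lesional/non-lesional PPI case
# study this pipeline was designed around. Point the four input paths at
# your own normalized log2 expression bundle and STRING-dialect edge
# export; every cutoff below carries the published value.
expression: data/expression.tsv      # probe x sample log2 intensities
design: data/design.tsv              # sample -> patient:condition (NL/LL)
probe_map: data/probe_map.tsv        # probe -> gene symbol
edges: data/string_edges.tsv         # node1, node2, combined_score

# DEG stage: p < 0.01, FDR < 0.01, |logFC| >= 1, top 2000
p_max: 0.01
fdr_max: 0.01
min_abs_logfc: 1.0
top_n: 2000

# network build: STRING combined score >= 0.4
min_combined_score: 0.4

# primary communicative genes on the full DEG network (union of metrics)
primary_thresholds:
  degree: 50
  stress: 200000
  eigenvector: 0.05

# macro level
resolution: 1.0
seed: 0
rel_var_min: 0.05

# per-module top communicative gene thresholds on the re-induced network
# (module ids follow the detected partition; swap if your module order
# differs — module 0 here carries the cell-cycle settings, module 1 the
# immune-system settings)
module_thresholds:
  0:
    degree: 87
    stress: 8732
    betweenness: 0.03
  1:
    degree: 26
    eigenvector: 0.007
    stress: 8518
    betweenness: 0.04

outdir: runs/replication
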