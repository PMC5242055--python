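# Full model: adds gene-body methylation and enhancer intervals to the
# reduced model. Enhancer evidence is weighted highest and direction-agnostic
# (no assumed relationship between enhancer methylation and expression);
# gene bodies are expected to move with expression.
genes_bed: fixture/genes.bed
expression: fixture/expression.tsv
expression_weight: 1.0
expression_direction: 1
tracks:
  meth: {path: fixture/methylation.tsv, one_based: false}
network_edges: fixture/network_edges.tsv
contexts:
  - {name: promoter, track: meth, rule: promoter_window,
     upstream_bp: 1000, downstream_bp: 500, weight: 0.5, direction: -1}
  - {name: body, track: meth, rule: gene_body, weight: 0.25, direction: 1}
  - {name: enhancer, track: meth, rule: custom_bed,
     bed_path: fixture/enhancers.bed, flank_bp: 500, max_link_distance: 50000,
     weight: 1.5, direction: 0}
normalization: logit_rescale
module_algorithm: both
gamma: 0.5
min_module_size: 8
max_module_size: 100
high_score_alpha: 0.05
seed: 1
out_dir: run_full
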