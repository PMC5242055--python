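# Reduced model: gene expression and promoter DNA methylation, equally
# weighted, in opposite directions (promoter methylation up ~ expression
# down). Paths are relative to where you run the pipeline.
genes_bed: fixture/genes.bed
expression: fixture/expression.tsv
expression_weight: 1.0
expression_direction: 1
tracks:
  meth: {path: fixture/methylation.tsv, one_based: false}
network_edges: fixture/network_edges.tsv
contexts:
  - {name: promoter, track: meth, rule: promoter_window,
     upstream_bp: 1000, downstream_bp: 500, weight: 1.0, direction: -1}
normalization: logit_rescale
module_algorithm: spinglass
gamma: 0.5
min_module_size: 8
max_module_size: 100
seed: 1
out_dir: run_reduced
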