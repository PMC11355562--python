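# Demo end-to-end run: simulate a planted-CN tissue, identify with CNE,
# smooth, and evaluate.  Run with:  cnkit pipeline --config examples/pipeline.yaml --outdir out/
seed: 0
simulate:
  n_cells: 2000
  n_cns: 4
  noise: 0.1
identify:
  method: cne
  k: 4
  perp: 15.0
smooth:
  method: naive
evaluate: {}
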