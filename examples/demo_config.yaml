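# Run configuration for the simulated demo bundle.  Place this file next to
# the layer tables written by `holocorr simulate` (paths resolve relative to
# this file).
layers:
  - id: host
    path: host.tsv
  - id: micro
    path: micro.tsv
  - id: metat
    path: metat.tsv
central_layer: host
metadata:
  path: metadata.tsv
network:
  power: 6            # fixed soft threshold; planted Gaussian modules are
  min_module_size: 15 # not scale-free, so the automatic scan is uninformative
correlation:
  method: pearson
  use: pairwise.complete.obs
  adjust: fdr
  annotation: asterisks
figure:
  format: svg
  distance: correlation
  linkage: average
  scaling: row-z
  sample_annotation: water
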