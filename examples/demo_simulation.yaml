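# Three-layer synthetic holobiont study: host transcriptome-like layer,
# microbial community layer and a metatranscriptome-like layer, with two
# planted cross-layer couplings and metadata tied to host modules.
n_samples: 40
layers:
  - layer_id: host
    modules:
      - {module_id: A1, n_features: 30, loading: 0.85}
      - {module_id: A2, n_features: 30, loading: 0.85}
      - {module_id: A3, n_features: 30, loading: 0.85}
      - {module_id: A4, n_features: 30, loading: 0.85}
    n_background_features: 30
  - layer_id: micro
    modules:
      - {module_id: B1, n_features: 30, loading: 0.85}
      - {module_id: B2, n_features: 30, loading: 0.85}
      - {module_id: B3, n_features: 30, loading: 0.85}
    n_background_features: 30
  - layer_id: metat
    modules:
      - {module_id: C1, n_features: 30, loading: 0.85}
      - {module_id: C2, n_features: 30, loading: 0.85}
    n_background_features: 20
couplings:
  - {layer_a: host, module_a: A1, layer_b: micro, module_b: B1, rho: 0.8}
  - {layer_a: host, module_a: A2, layer_b: metat, module_b: C1, rho: 0.7}
metadata_links:
  - {name: weight, layer: host, module: A1, effect: 0.8, kind: numeric}
  - {name: water, layer: host, module: A2, effect: 0.9, kind: binary}
n_free_metadata: 1
missing_rate: 0.0
seed: 42
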