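# CPU-scale experiment: two-layer network, 48x48 frames, propeller and
# snake probes.  Run with:
#   predflow run-all --config examples/toy_config.yaml --seed 1 --out runs/toy
network:
  n_layers: 2
  stack_sizes: [3, 16]
  input_shape: [48, 48, 3]
  seed: 1

corpus:
  seed: 2
  n_frames: 4000
  size: [48, 48]
  clip_len: 60
  rotation_fraction: 0.35
  disc_fraction: 0.25

flow:
  window_size: 21
  quality_level: 0.15
  max_features: 50
  min_distance: 4

total_frames: 20000
checkpoint_every: 2000
analysis_window: [12000, 20000]
seed: 1

probes:
  - name: propeller_cw
    kind: propeller
    spec: {rpm: 15.0, direction: cw, size: [48, 48]}
    expected_sign: 1
  - name: propeller_ccw
    kind: propeller
    spec: {rpm: 15.0, direction: ccw, size: [48, 48]}
    expected_sign: -1
  - name: propeller_static
    kind: propeller
    spec: {rpm: 0.0, size: [48, 48]}
    expected_sign: 0
  - name: snake_illusion
    kind: snake
    spec: {mode: illusion, size: [48, 48]}
    expected_sign: -1
    overlay_amplification: 60
  - name: snake_control
    kind: snake
    spec: {mode: control, size: [48, 48]}
    expected_sign: 0
    overlay_amplification: 60
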