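# Demo: generate a forearm phantom at the cadaveric study magnitudes and
# run the full measurement pipeline on it.
#   iomorph run --config examples/demo_config.yaml --out scratch/demo
seed: 1
pipeline:
  slab_width: 0.2
  station_step: 0.05
  preload: 0.5
  failure_stop_fraction: 0.95
phantom:
  mesh_resolution: 2.0
  truth:
    radius_length: 254.4
    ulna_length: 271.5
    gap: 16.4
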