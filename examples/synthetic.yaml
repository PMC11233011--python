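# Synthetic end-to-end example.
#
#   rapoport simulate examples/synthetic.yaml   # writes world to output_dir
#   rapoport run examples/synthetic_run.yaml    # analyses the written files
output_dir: demo_world
simulation:
  n_species: 40
  domain_extent: [0, 0, 1000, 2000]
  cell_size: 50.0
  beta_rapoport: 0.6
  lambda_true: 0.0
  records_per_cell: 4.0
  seed: 7
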