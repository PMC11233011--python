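# Analyse the world written by `rapoport simulate examples/synthetic.yaml`.
occurrences_path: demo_world/occurrences.csv
tree_path: demo_world/tree.nwk
env_raster_paths:
  min_temp: demo_world/env_min_temp.asc
  temp_annual_range: demo_world/env_temp_annual_range.asc
  elevation: demo_world/env_elevation.asc
  mat: demo_world/env_mat.asc
  mat_past: demo_world/env_mat_past.asc
output_dir: demo_world/analysis
crs: projected-km
grid_extent: [0, 0, 1000, 2000]
cell_size: 50.0
thinning_resolution: null
range_method: alpha_hull
buffer_km: 0.0
alpha0: 25.0
n_rep: 50
signal_n_perm: 199
models: [ols, pgls, sar]
null_models: [ols]
seed: 7
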