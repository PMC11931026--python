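# End-to-end synthetic demo at desk scale (one CPU core, a few minutes).
out_dir: runs/demo
seed: 0
simulate: true
scene:
  n_per_ring: 20
  height: 64
  width: 64
  n_quad: 128
  n_leaves: 12
  n_heldout: 1
keyframes:
  # the synthetic capture has 20 frames per view; keep most of them
  target_per_view: 20
  per_view: 18
train:
  n_iters: 2000
  batch_rays: 384
  n_coarse: 24
  n_fine: 40
  field:
    fine_grid: {n_levels: 16, log2_table_size: 15, finest: 2048}
    coarse_grid: {n_levels: 8, log2_table_size: 13, finest: 512}
    density_hidden: 32
    color_hidden: 32
    coarse_hidden: 16
mesh:
  grid_resolution: 128
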