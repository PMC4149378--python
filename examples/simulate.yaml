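# End-to-end run on a simulated phantom: annular ventricular wall,
# 11 um voxels, scanned at the experimental staining times.
input: simulate
phantom:
  outer_radius: 3.0        # mm
  wall_thickness: 2.2      # mm
  voxel_size: 11.0         # um
  times: [0, 6, 13, 26, 39, 58]   # h
  background_level: 1000   # counts
  noise_sd: 0.0            # counts; set ~200 for 1% of dynamic range
  beam_hardening_slope: 2000   # counts per mm of depth
  seed: 0
model:
  I0: 10000                # unstained intensity, counts
  Imax_surface: 30000      # saturated intensity at the surface, counts
  tau_surface: 5.0         # h
  tau_depth_rate: 1.0      # per mm
edge:
  sigma_px: 1.0
  drop_fraction: 0.25
  reference_timepoint: last
segments:
  seg_len_mm: 0.1
  n_segments: 20
levels: [0.90, 0.95, 0.99]
seed: 0
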