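# Demo pipeline: synthesize a coarse 4-shell sphere phantom with a superficial
# target blob and a deep avoid blob, place 4 electrodes, solve the basis,
# optimize the montage, and export region statistics.
out_dir: demo_out
phantom:
  kind: sphere
  voxel_mm: 5.0
  target_blobs:
    - {center_mm: [30.0, 18.0, 30.0], radius_mm: 12.0, name: target}
  avoid_blobs:
    - {center_mm: [0.0, 0.0, -10.0], radius_mm: 12.0, name: avoid}
montage_n: 4
montage_area_cm2: 16.0
problem:
  target: [target]
  avoid: [avoid]
  J_max: 5.0e-4
  C_min: 0.5
  C_max: 2.0
  r: 2.0
settings:
  n_restarts: 2
reduce_k: [2]
report_regions:
  gray_matter: gray_matter
  skin: skin
seed: 11
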