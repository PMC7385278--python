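# Demo study configuration for `fibroct run --config examples/demo_study.yaml`:
# three arms of three animals on a 64-voxel grid, imaged at days 7/14/21.
out_dir: scratch/demo_study
rng_seed: 0
grid: 64
days: [7, 14, 21]
groups:
  - {name: saline, route: none, bleomycin: false, n_animals: 3}
  - {name: BLM, route: OA, n_animals: 3}
  - {name: BLM+drug, route: OA, treatment: drug, n_animals: 3}
control_group: saline
disease_group: BLM
treated_group: BLM+drug
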