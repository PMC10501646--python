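# Small end-to-end configuration: subdivision-4 meshes, five subjects.
# Usable for a quick full-pipeline run:
#   brocamorph simulate --config configs/small.yaml --seed 7 --out scratch/sim
species_a:
  subdiv_level: 4
  radius_mm: 40.0
  gyri_amplitude_mm: 2.5
species_b:
  subdiv_level: 4
  radius_mm: 55.0
  gyri_amplitude_mm: 3.2
population:
  n_subjects: 5
  warp_amplitude: 0.05
  label_jitter: 1
pair:
  expansion: 1.6
  shift_deg: 20.0
registration:
  lambda_smooth: 0.1
  levels: [2, 3, 4]
  max_iter_per_level: 100
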