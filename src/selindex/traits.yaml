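# Versioned trait catalogue: condensation maps for behavior traits,
# per-trait correlations with training success, and Total Score weights.
version: 1

index_weights:
  w_health: 0.02
  w_behavior: 0.324

standardization:
  pace:
    "Fast": 2
    "Above average": 2
    "High average": 2
    "Average": 1
    "Less than average": 0
  distraction:
    "High": 1
    "Above average": 1
    "Average": 0
    "Less than average": 0
  pull:
    "Hard": 2
    "Above average": 2
    "Average": 1
    "Defined average": 1
    "Less than average": 0
  neck:
    "Hard": 2
    "Above average": 2
    "Average": 1
    "Less than average": 0
    "Easy": 0
  rating:
    "5": 7
    "4+": 6
    "4": 5
    "4-": 4
    "3+": 3
    "3": 2
    "3-": 1
    "2+": 0
  soundness:
    "Sound": 2
    "Above average": 1
    "Average": 0
    "Less than average": 0

traits:
  base_narrow_mandibular_canines:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.026, category_group: dental}
  malocclusion_class_i:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.035, category_group: dental}
  supernumerary_teeth:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.024, category_group: dental}
  retained_deciduous_teeth:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.013, category_group: dental}
  anodontia:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.014, category_group: dental}
  mandibular_distocclusion:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.105, category_group: dental}
  mandibular_prognathism:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.031, category_group: dental}
  mandibular_mesiocclusion:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.047, category_group: dental}
  distichiasis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.032, category_group: ocular}
  ppm:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.025, category_group: ocular}
  histiocytoma:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.036, category_group: dermal}
  atopic_dermatitis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.1, category_group: dermal}
  allergic_dermatitis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.009, category_group: dermal}
  alopecia_bridge_of_nose:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.027, category_group: dermal}
  acral_lick_dermatitis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.029, category_group: dermal}
  muzzle_folliculitis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.009, category_group: dermal}
  loose_interphalangeal_collateral_ligaments:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.003, category_group: neuro_musculoskeletal}
  panosteitis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.02, category_group: neuro_musculoskeletal}
  umbilical_hernia:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.009, category_group: other}
  oral_papillomatosis:
    {kind: binary_health, direction: negative, x_max: 1, weight_r: -0.02, category_group: other}
  neck:
    {kind: ordinal_behavior, direction: negative, x_max: 2, weight_r: -0.108, category_group: behavior}
  distraction:
    {kind: ordinal_behavior, direction: negative, x_max: 1, weight_r: -0.107, category_group: behavior}
  rating:
    {kind: ordinal_behavior, direction: negative, x_max: 7, weight_r: -0.144, category_group: behavior}
  soundness:
    {kind: ordinal_behavior, direction: positive, x_max: 2, weight_r: 0.127, category_group: behavior}
  trainability:
    {kind: ordinal_behavior, direction: positive, x_max: 4, weight_r: 0.531, category_group: behavior}
  pace:
    {kind: ordinal_behavior, direction: neutral, x_max: 2, weight_r: 0.02, category_group: behavior}
  pull:
    {kind: ordinal_behavior, direction: neutral, x_max: 2, weight_r: 0.017, category_group: behavior}
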