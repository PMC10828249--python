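# Default 40-item deficit catalog for the deficit-accumulation frailty index:
# 16 activities-of-daily-living items, 10 chronic-disease items, 14 other
# physical/mental-health deficits. Four items have documented special handling
# (the arthritis any-of composite; osteoporosis and breathlessness, both
# unavailable from wave 5 onward; the 5-level self-perceived-health item with
# equal-step ordinal scoring). The remaining item names are SYNTHETIC
# placeholders (marked `synthetic: true`): plausible survey-item names standing
# in for the full published item list, which is not reproduced here. The scoring
# engine is item-agnostic; edit or replace this file to use a transcribed list.
#
# Unless `waves` is given, an item is available in waves [1, 2, 4, 5, 6, 8].
provenance: >
  Default catalog honouring the published 16/10/14 group structure; unnamed
  items are synthetic placeholders.
items:
  # --- activities of daily living (16) ---
  - {name: difficulty_dressing, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_walking_across_room, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_bathing, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_eating, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_bed_transfer, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_using_toilet, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_preparing_meal, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_shopping, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_phone_calls, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_taking_medication, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_housework, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_managing_money, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_walking_100m, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_climbing_stairs, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_stooping, group: ADL, value_type: binary, synthetic: true}
  - {name: difficulty_lifting_5kg, group: ADL, value_type: binary, synthetic: true}
  # --- chronic diseases (10) ---
  - name: arthritis
    group: chronic_disease
    value_type: composite_any
    components: [rheumatoid_arthritis, osteoarthritis]
  - name: osteoporosis
    group: chronic_disease
    value_type: binary
    waves: [1, 2, 4]
  - {name: heart_attack, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: hypertension, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: high_cholesterol, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: stroke, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: diabetes, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: chronic_lung_disease, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: cancer, group: chronic_disease, value_type: binary, synthetic: true}
  - {name: stomach_ulcer, group: chronic_disease, value_type: binary, synthetic: true}
  # --- other physical and mental health deficits (14) ---
  - name: breathlessness
    group: other
    value_type: binary
    waves: [1, 2, 4]
  - name: self_perceived_health
    group: other
    value_type: ordinal5
  - {name: trouble_sleeping, group: other, value_type: binary, synthetic: true}
  - {name: falls, group: other, value_type: binary, synthetic: true}
  - {name: dizziness, group: other, value_type: binary, synthetic: true}
  - {name: incontinence, group: other, value_type: binary, synthetic: true}
  - {name: poor_appetite, group: other, value_type: binary, synthetic: true}
  - {name: sadness_depression, group: other, value_type: binary, synthetic: true}
  - {name: pessimism, group: other, value_type: binary, synthetic: true}
  - {name: irritability, group: other, value_type: binary, synthetic: true}
  - {name: poor_concentration, group: other, value_type: binary, synthetic: true}
  - {name: poor_memory, group: other, value_type: binary, synthetic: true}
  - {name: low_energy, group: other, value_type: binary, synthetic: true}
  - {name: tearfulness, group: other, value_type: binary, synthetic: true}
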