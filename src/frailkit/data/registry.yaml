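# Default 30-item deficit registry for the FI-30 instrument.
# Each item: id, short name, data source, and the ordered label -> weight coding.
# Weights follow the deficit-accumulation convention: 0 = deficit absent,
# 1 = deficit fully present, intermediate grades for partial severity.
items:
  - item_id: 1
    name: self_rated_health
    source: self-report
    levels: [[Good, 0.0], [Average, 0.5], [Poor Health, 1.0]]
  - item_id: 2
    name: hearing_difficulty
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 3
    name: cataracts
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 4
    name: vision_difficulty
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 5
    name: anemia
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 6
    name: angina
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 7
    name: asthma
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 8
    name: balance_assistance
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 9
    name: bathing_assistance
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 10
    name: bmi_grade
    source: biomarker
    levels: [[Normal, 0.0], [Moderate, 0.5], [Severe, 1.0]]
  - item_id: 11
    name: bronchitis
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 12
    name: chair_stand_difficulty
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 13
    name: arthritis
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 14
    name: toilet_assistance
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 15
    name: loneliness
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 16
    name: carrying_help
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 17
    name: rbs_grade
    source: biomarker
    levels: [[Normal, 0.0], [Elevated, 0.5], [High, 1.0]]
  - item_id: 18
    name: dressing_assistance
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 19
    name: walking_stick
    source: performance
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 20
    name: gds_grade
    source: self-report
    levels: [[Normal depression, 0.0], [Moderate depression, 0.5], [Severe depression, 1.0]]
  - item_id: 21
    name: heart_attack
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 22
    name: hbp_grade
    source: biomarker
    levels: [[Normal, 0.0], [Mild, 0.33], [Moderate, 0.66], [Severe, 1.0]]
  - item_id: 23
    name: heart_murmur
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 24
    name: heart_problem
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 25
    name: kidney_disease
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 26
    name: liver_disease
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 27
    name: osteoporosis
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 28
    name: seizure
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 29
    name: stroke
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
  - item_id: 30
    name: urinary_infection
    source: self-report
    levels: [["No", 0.0], ["Yes", 1.0]]
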