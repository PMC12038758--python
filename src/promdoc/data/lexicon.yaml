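# Default PROM catalog: 18 validated pain/function instruments commonly used
# in spine care (15 seed measures plus 3 added during rule refinement:
# the PEG, the Patient-Specific Functional Scale, and the DVPRS).
# Unidimensional pain intensity scales (NRS, VAS) are deliberately excluded.
# Sites should align this inventory with their local instrument list.
definitions:
  - prom_id: odi
    canonical_name: Oswestry Disability Index
    aliases:
      - Oswestry Disability Index
      - Oswestry Disability Questionnaire
      - Oswestry
    abbreviations: [ODI]
    allow_fuzzy: true
    category: function
  - prom_id: bournemouth_back
    canonical_name: Bournemouth Questionnaire (back)
    aliases:
      - Bournemouth Questionnaire back
      - Bournemouth Back Questionnaire
      - Bournemouth back
      - Bournemouth Questionnaire
    abbreviations: [BQB, BQ]
    allow_fuzzy: true
    category: multidimensional
  - prom_id: bournemouth_neck
    canonical_name: Bournemouth Questionnaire (neck)
    aliases:
      - Bournemouth Questionnaire neck
      - Bournemouth Neck Questionnaire
      - Bournemouth neck
    abbreviations: [BQN]
    allow_fuzzy: true
    category: multidimensional
  - prom_id: ndi
    canonical_name: Neck Disability Index
    aliases:
      - Neck Disability Index
    abbreviations: [NDI]
    allow_fuzzy: true
    category: function
  - prom_id: rmdq
    canonical_name: Roland-Morris Disability Questionnaire
    aliases:
      - Roland-Morris Disability Questionnaire
      - Roland Morris Disability Questionnaire
      - Roland-Morris
    abbreviations: [RMDQ, RDQ]
    allow_fuzzy: true
    category: function
  - prom_id: promis_pf
    canonical_name: PROMIS Physical Function
    aliases:
      - PROMIS Physical Function
      - PROMIS physical function short form
    abbreviations: [PROMIS]
    allow_fuzzy: false
    category: function
  - prom_id: pcs
    canonical_name: Pain Catastrophizing Scale
    aliases:
      - Pain Catastrophizing Scale
    abbreviations: [PCS]
    allow_fuzzy: true
    category: psychological
  - prom_id: fabq
    canonical_name: Fear-Avoidance Beliefs Questionnaire
    aliases:
      - Fear-Avoidance Beliefs Questionnaire
      - Fear Avoidance Beliefs Questionnaire
    abbreviations: [FABQ]
    allow_fuzzy: true
    category: psychological
  - prom_id: bpi
    canonical_name: Brief Pain Inventory
    aliases:
      - Brief Pain Inventory
    abbreviations: [BPI]
    allow_fuzzy: true
    category: pain
  - prom_id: qbpds
    canonical_name: Quebec Back Pain Disability Scale
    aliases:
      - Quebec Back Pain Disability Scale
      - Quebec Disability Scale
    abbreviations: [QBPDS]
    allow_fuzzy: true
    category: function
  - prom_id: start_back
    canonical_name: STarT Back Screening Tool
    aliases:
      - STarT Back Screening Tool
      - Keele STarT Back
    abbreviations: [SBST]
    allow_fuzzy: false
    category: screening
  - prom_id: phq9
    canonical_name: Patient Health Questionnaire-9
    aliases:
      - Patient Health Questionnaire-9
      - Patient Health Questionnaire 9
    abbreviations: [PHQ-9, PHQ9]
    allow_fuzzy: false
    category: psychological
  - prom_id: gad7
    canonical_name: Generalized Anxiety Disorder-7
    aliases:
      - Generalized Anxiety Disorder-7
      - Generalized Anxiety Disorder 7
    abbreviations: [GAD-7, GAD7]
    allow_fuzzy: false
    category: psychological
  - prom_id: hit6
    canonical_name: Headache Impact Test
    aliases:
      - Headache Impact Test
    abbreviations: [HIT-6, HIT6]
    allow_fuzzy: true
    category: pain
  - prom_id: whodas
    canonical_name: WHO Disability Assessment Schedule
    aliases:
      - WHO Disability Assessment Schedule
      - WHODAS 2.0
    abbreviations: [WHODAS]
    allow_fuzzy: false
    category: function
  - prom_id: peg
    canonical_name: Pain, Enjoyment, General Activity scale
    aliases:
      - Pain Enjoyment General Activity
      - PEG scale
    abbreviations: [PEG]
    allow_fuzzy: false
    category: pain
  - prom_id: psfs
    canonical_name: Patient-Specific Functional Scale
    aliases:
      - Patient-Specific Functional Scale
      - Patient Specific Functional Scale
    abbreviations: [PSFS]
    allow_fuzzy: true
    category: function
  - prom_id: dvprs
    canonical_name: Defense and Veterans Pain Rating Scale
    aliases:
      - Defense and Veterans Pain Rating Scale
    abbreviations: [DVPRS]
    allow_fuzzy: true
    category: pain
excluded_measures:
  - Numerical Rating Scale
  - Numeric Rating Scale
  - NRS
  - Visual Analog Scale
  - Visual Analogue Scale
  - VAS
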