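# Default obstetrics rulebook: 17 rules covering value conformance and
# domain plausibility.  Ranges marked ASSUMED are defaults chosen where the
# clinical team would normally supply bounds; override by shipping your own
# rulebook file.
rules:
  # --- conformance -------------------------------------------------------
  - id: R01_dob_format
    dimension: conformance
    description: Maternal date of birth must be written day/month/year (4-digit year).
    kind: date_format
    column: maternal_dob
    format: d/m/Y
  - id: R02_robson_value_set
    dimension: conformance
    description: Robson group must be one of the 10 classification groups.
    kind: value_set
    columns: [robson_group]
    values: ["1", "2", "3", "4", "5", "6", "7", "8", "9", "10"]
  - id: R03_bishop_value_set
    dimension: conformance
    description: Bishop score is an integer between 0 and 13.
    kind: numeric_range
    columns: [bishop_score]
    min: 0
    max: 13
    integer: true
  - id: R04_delivery_type_value_set
    dimension: conformance
    description: Delivery type must use the admissible codes.
    kind: value_set
    columns: [delivery_type]
    values: [eutocic, vacuum, forceps, cesarean]
  - id: R05_fetal_position_value_set
    dimension: conformance
    description: Fetal position codes (admission and delivery) must be admissible.
    kind: value_set
    columns: [fetal_position_admission, fetal_position_delivery]
    values: [cephalic, breech, transverse]
  - id: R06_blood_group_value_set
    dimension: conformance
    description: Maternal blood group must be a valid ABO/Rh code.
    kind: value_set
    columns: [blood_group]
    values: [A+, A-, B+, B-, AB+, AB-, O+, O-]
  - id: R07_pregnancy_type_value_set
    dimension: conformance
    description: Pregnancy type must be single or multiple.
    kind: value_set
    columns: [pregnancy_type]
    values: [single, multiple]
  - id: R08_count_columns_numeric
    dimension: conformance
    description: Count columns must hold non-negative integers.
    kind: numeric_range
    columns:
      [parity, n_pregnancies, n_prev_eutocic, n_prev_csections,
       n_prenatal_visits, n_deliveries_vacuum]
    min: 0
    integer: true
  # --- plausibility ------------------------------------------------------
  - id: P09_gestational_age_delivery
    dimension: plausibility
    description: Gestational age at delivery between 20 and 44 weeks.
    kind: numeric_range
    columns: [gestational_age_delivery]
    min: 20
    max: 44
  - id: P10_gestational_age_admission
    dimension: plausibility
    description: Gestational age at admission between 20 and 44 weeks.
    kind: numeric_range
    columns: [gestational_age_admission]
    min: 20
    max: 44
  - id: P11_maternal_weight_range
    dimension: plausibility
    description: Maternal weight between 30 and 250 kg (ASSUMED bounds).
    kind: numeric_range
    columns: [maternal_weight]
    min: 30
    max: 250
  - id: P12_bmi_range
    dimension: plausibility
    description: Body-mass index between 12 and 70 kg/m^2 (ASSUMED bounds).
    kind: numeric_range
    columns: [bmi]
    min: 12
    max: 70
  - id: P13_maternal_age_range
    dimension: plausibility
    description: Maternal age between 10 and 60 years (ASSUMED bounds).
    kind: numeric_range
    columns: [maternal_age]
    min: 10
    max: 60
  - id: P14_parity_consistency
    dimension: plausibility
    description: Previous deliveries cannot exceed previous pregnancies.
    kind: cross_column_comparison
    left: parity
    right: n_pregnancies
    op: le
  - id: P15_efw_week35_gt_week25
    dimension: plausibility
    description: Estimated fetal weight at week 35 must exceed the week-25 estimate.
    kind: cross_column_comparison
    left: efw_week25
    right: efw_week35
    op: lt
  - id: P16_efw_series_increasing
    dimension: plausibility
    description: Ultrasound weight estimates more than 5 weeks apart must be strictly increasing.
    kind: monotone_series
    columns: [efw_week25, efw_week30, efw_week35]
    spacing: [25, 30, 35]
    min_separation: 5
  - id: P17_admission_before_delivery
    dimension: plausibility
    description: Gestational age at admission cannot exceed gestational age at delivery.
    kind: cross_column_comparison
    left: gestational_age_admission
    right: gestational_age_delivery
    op: le
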