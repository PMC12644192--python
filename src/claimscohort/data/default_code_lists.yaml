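# Synthetic placeholder code lists for the claimscohort pipeline.
#
# These stand in for proprietary code dictionaries (diagnosis code lists for
# infections / breast cancer / HER2 status, intravenous antibacterial drug
# lists, and a comorbidity-index weight map).  Code VALUES are invented;
# the structure (hierarchical diagnosis prefixes, flat drug code lists,
# weighted comorbidity categories) mirrors real configurations and every
# list is replaceable via `load_code_lists`.
code_lists:
  breast_cancer:
    match: prefix
    codes: [C50]
  her2_positive:
    match: prefix
    codes: [C50H]
  infection:
    match: prefix
    codes: [A4, B9, J1, N39, U07]
  covid19:
    match: prefix
    codes: [U07]
  iv_antibacterial:
    match: exact
    codes: [ABX01, ABX02, ABX03, ABX04, ABX05]
  study_drug:
    atezolizumab:
      match: exact
      codes: [ATEZ]
    nab_paclitaxel:
      match: exact
      codes: [NABP]
  other_anticancer:
    match: exact
    codes: [OANC1, OANC2]
  adjuvant_chemo:
    match: exact
    codes: [ADJC1]
  other_regimen:
    match: exact
    codes: [OREG1]
  anticancer_history:
    match: exact
    codes: [HANC1, HANC2]
  steroid:
    match: exact
    codes: [STER1, STER2]
  covariate_diagnosis:
    renal_impairment:
      match: prefix
      codes: [N18]
    hepatic_impairment:
      match: prefix
      codes: [K72]
    lymph_node_metastasis:
      match: prefix
      codes: [C77]
    diabetes:
      match: prefix
      codes: [E11]
  # 17 comorbidity categories with standard index weights; placeholder
  # code families CM01..CM17 keep the map disjoint from the covariate lists.
  comorbidity_map:
    - {pattern: CM01, category: myocardial_infarction, weight: 1}
    - {pattern: CM02, category: congestive_heart_failure, weight: 1}
    - {pattern: CM03, category: peripheral_vascular_disease, weight: 1}
    - {pattern: CM04, category: cerebrovascular_disease, weight: 1}
    - {pattern: CM05, category: dementia, weight: 1}
    - {pattern: CM06, category: chronic_pulmonary_disease, weight: 1}
    - {pattern: CM07, category: rheumatic_disease, weight: 1}
    - {pattern: CM08, category: peptic_ulcer_disease, weight: 1}
    - {pattern: CM09, category: mild_liver_disease, weight: 1}
    - {pattern: CM10, category: diabetes_uncomplicated, weight: 1}
    - {pattern: CM11, category: diabetes_complicated, weight: 2}
    - {pattern: CM12, category: hemiplegia, weight: 2}
    - {pattern: CM13, category: renal_disease, weight: 2}
    - {pattern: CM14, category: any_malignancy, weight: 2}
    - {pattern: CM15, category: moderate_severe_liver_disease, weight: 3}
    - {pattern: CM16, category: metastatic_solid_tumour, weight: 6}
    - {pattern: CM17, category: aids_hiv, weight: 6}
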