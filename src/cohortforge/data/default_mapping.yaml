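# Default study-dialect mapping and variable-availability configuration.
#
# `availability_exceptions` lists, per CDM variable, the studies in which the
# variable is structurally unavailable (never collected); every other
# (study, variable) pair is available.  `dialects` maps each study's source
# column names and value codings onto the common data model; unknown source
# codes are hard errors during harmonisation, never silently coerced.

studies: [BCRD, BSPAR-Et, CAPS, CHARMS]

availability_exceptions:
  pain_vas: [CHARMS]
  stop_reason: [CHARMS]
  date_of_diagnosis: [CAPS, CHARMS]
  date_of_symptom_onset: [BCRD, BSPAR-Et]
  route: [BCRD, BSPAR-Et]

# canonical lowercase drug name -> drug class
drug_classes:
  methotrexate: MTX
  etanercept: TNFi
  adalimumab: TNFi
  infliximab: TNFi
  golimumab: TNFi
  tocilizumab: other_biologic

dialects:
  BCRD:
    id_prefix: B
    columns:
      patients:
        local_id: bcrd_id
        nhs_number: nhs_no
        date_of_birth: dob
        gender: sex
        ethnicity: ethnic_origin
        ilar_subtype: ilar_code
        date_of_diagnosis: diagnosis_date
        ana: ana
        rf: rf
        hla_b27: hla_b27
        uveitis_ever: uveitis
      visits:
        local_id: bcrd_id
        visit_date: visit_date
        ajc: active_jts
        ljc: limited_jts
        chaq: chaq
        esr: esr
        crp: crp
        pga: phys_global
        pge: parent_global
        pain_vas: pain_vas
        height_cm: height
        weight_kg: weight
      episodes:
        local_id: bcrd_id
        drug_name: drug
        start_date: start_date
        stop_date: stop_date
        dose_value: dose
        dose_unit: dose_unit
        stop_reason: stop_reason
    values:
      gender: {M: male, F: female}
      ethnicity: {White: Caucasian, Non-White: Non-Caucasian}
      ilar_subtype:
        "1": systemic
        "2": oligo_persistent
        "3": oligo_extended
        "4": poly_rf_neg
        "5": poly_rf_pos
        "6": enthesitis_related
        "7": psoriatic
        "8": undifferentiated
      tristate: {Y: positive, N: negative}
      uveitis: {Y: "yes", N: "no"}
      stop_reason: {INEFF: inefficacy, AE: adverse_event, REM: remission, OTH: other}
      drug:
        MTX: methotrexate
        ETA: etanercept
        ADA: adalimumab
        INF: infliximab
        GOL: golimumab
        TOC: tocilizumab

  BSPAR-Et:
    id_prefix: E
    columns:
      patients:
        local_id: subject_id
        nhs_number: nhs_number
        date_of_birth: date_of_birth
        gender: gender
        ethnicity: ethnicity
        ilar_subtype: ilar
        date_of_diagnosis: date_of_diagnosis
        ana: ana_status
        rf: rf_status
        hla_b27: hla_b27_status
        uveitis_ever: uveitis_ever
      visits:
        local_id: subject_id
        visit_date: date_of_visit
        ajc: active_joint_count
        ljc: limited_joint_count
        chaq: chaq_score
        esr: esr_mm_hr
        crp: crp_mg_l
        pga: physician_global
        pge: patient_global
        pain_vas: pain_vas
        height_cm: height_cm
        weight_kg: weight_kg
      episodes:
        local_id: subject_id
        drug_name: drug_name
        start_date: date_started
        stop_date: date_stopped
        dose_value: dose
        dose_unit: dose_units
        stop_reason: reason_stopped
    values:
      gender: {Male: male, Female: female}
      ethnicity: {Caucasian: Caucasian, Other: Non-Caucasian}
      ilar_subtype:
        "1": systemic
        "2": oligo_persistent
        "3": oligo_extended
        "4": poly_rf_neg
        "5": poly_rf_pos
        "6": enthesitis_related
        "7": psoriatic
        "8": undifferentiated
      tristate: {Positive: positive, Negative: negative}
      uveitis: {"Yes": "yes", "No": "no"}
      stop_reason:
        Ineffective: inefficacy
        Adverse event: adverse_event
        Remission: remission
        Other: other
      drug:
        Methotrexate: methotrexate
        Etanercept: etanercept
        Adalimumab: adalimumab
        Infliximab: infliximab
        Golimumab: golimumab
        Tocilizumab: tocilizumab

  CAPS:
    id_prefix: C
    columns:
      patients:
        local_id: caps_id
        nhs_number: nhsno
        date_of_birth: birth_date
        gender: sex
        ethnicity: ethnic_group
        ilar_subtype: ilar_category
        date_of_symptom_onset: symptom_onset_date
        ana: ana
        rf: rf
        hla_b27: hlab27
        uveitis_ever: uveitis
      visits:
        local_id: caps_id
        visit_date: assess_date
        ajc: ajc
        ljc: ljc
        chaq: chaq
        esr: esr
        crp: crp
        pga: pga
        pge: pge
        pain_vas: pain_score
        height_cm: ht_cm
        weight_kg: wt_kg
      episodes:
        local_id: caps_id
        drug_name: medication
        start_date: med_start
        stop_date: med_stop
        dose_value: dose_amount
        dose_unit: dose_unit
        stop_reason: stop_code
        route: route
    values:
      gender: {"1": male, "2": female}
      ethnicity:
        White British: Caucasian
        White Other: Caucasian
        Indian: Non-Caucasian
        Pakistani: Non-Caucasian
        Bangladeshi: Non-Caucasian
        Black Caribbean: Non-Caucasian
        Black African: Non-Caucasian
        Chinese: Non-Caucasian
        Mixed: Non-Caucasian
        Other: Non-Caucasian
      ilar_subtype:
        Systemic arthritis: systemic
        Persistent oligoarthritis: oligo_persistent
        Extended oligoarthritis: oligo_extended
        RF-negative polyarthritis: poly_rf_neg
        RF-positive polyarthritis: poly_rf_pos
        Enthesitis-related arthritis: enthesitis_related
        Psoriatic arthritis: psoriatic
        Undifferentiated arthritis: undifferentiated
      tristate: {"1": positive, "0": negative}
      uveitis: {"1": "yes", "0": "no"}
      stop_reason: {"1": inefficacy, "2": adverse_event, "3": remission, "4": other}
      route: {O: oral, SC: subcutaneous}
      drug:
        methotrexate: methotrexate
        etanercept: etanercept
        adalimumab: adalimumab
        infliximab: infliximab
        golimumab: golimumab
        tocilizumab: tocilizumab

  CHARMS:
    id_prefix: H
    columns:
      patients:
        local_id: charms_id
        nhs_number: nhs
        date_of_birth: dob
        gender: sex
        ethnicity: ethnicity
        ilar_subtype: subtype
        date_of_symptom_onset: onset_date
        ana: ana_result
        rf: rf_result
        hla_b27: b27_result
        uveitis_ever: uveitis_hx
      visits:
        local_id: charms_id
        visit_date: visit_dt
        ajc: act_jts
        ljc: lim_jts
        chaq: chaq_total
        esr: esr_result
        crp: crp_result
        pga: md_global
        pge: pt_global
        height_cm: height
        weight_kg: weight
      episodes:
        local_id: charms_id
        drug_name: drug_code
        start_date: start_dt
        stop_date: stop_dt
        dose_value: dose_mg
        dose_unit: dose_unit
        route: route
    values:
      gender: {male: male, female: female}
      ethnicity:
        White: Caucasian
        Asian: Non-Caucasian
        Black: Non-Caucasian
        Mixed: Non-Caucasian
        Other: Non-Caucasian
      ilar_subtype:
        sJIA: systemic
        oligo-persistent: oligo_persistent
        oligo-extended: oligo_extended
        poly RF-: poly_rf_neg
        poly RF+: poly_rf_pos
        ERA: enthesitis_related
        PsA: psoriatic
        undiff: undifferentiated
      tristate: {pos: positive, neg: negative}
      uveitis: {"yes": "yes", "no": "no"}
      route: {oral: oral, subcut: subcutaneous}
      drug:
        MTX: methotrexate
        ETN: etanercept
        ADA: adalimumab
        IFX: infliximab
        GOL: golimumab
        TCZ: tocilizumab
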