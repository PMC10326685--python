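# Default imatinib drug / system / perpetrator configuration.
#
# Drug intrinsic-clearance and interaction constants are effective values
# calibrated so that the model reproduces its reference behaviour in a
# typical European adult: dilute-drug fu_p = 0.05 at AAG 0.91 g/L,
# steady-state CL/F ~ 9-10 L/h at 400 mg daily, a ~3% minor-CYP share of
# hepatic metabolism, and the documented steady-state sensitivity and
# interaction magnitudes.  Perpetrator PK parameters are literature-typical
# one-compartment reductions; inhibition/induction constants are effective
# in-vivo values on the unbound plasma concentration scale used by the
# engine.  Cohort-generator marginals (body size, creatinine, dose mix)
# are stand-ins, not estimates of any real cohort.

drug:
  name: imatinib
  molecular_weight_g_per_mol: 493.6
  ka_per_h: 0.61
  fa_fraction: 0.97
  blood_plasma_ratio: 0.9
  fu_ref_fraction: 0.05
  aag_ref_g_per_l: 0.91
  binding_capacity_sites_per_mol: 1.0
  aag_molecular_weight_g_per_mol: 44000.0
  clint_per_pmol_ul_per_min:          # unbound CLint per pmol enzyme
    CYP3A4_hepatic: 0.1290
    CYP2C8_hepatic: 0.6830
    CYP3A4_gut: 0.0133
    other_CYP: 0.8440                 # fixed pseudo-abundance of 1 pmol/mg
  clint_biliary_l_per_h_per_unit:     # per (pmol / 1e6 hepatocytes), at reference liver
    P-gp: 262.0
    BCRP: 262.0
  cl_renal_ref_l_per_h: 0.40          # at eGFR 100 mL/min/1.73m2 and BSA 1.73 m2
  renal_fu_scaling: false             # empirical patient CL_R applied per GFR only
  autoinhibition:                     # CYP3A4 mechanism-based autoinactivation
    KI_uM: 2.0
    kinact_per_h: 0.25
  vc_per_kg_l: 1.35
  vp_per_kg_l: 1.95
  q_inter_l_per_h: 14.0
  liver_kp_blood: 15.0                # liver : emergent venous blood partition
  gut_transit_per_h: 1.0              # gut wall -> portal first-order transfer
  gut_wall_volume_l: 1.0

system:
  qh_ref_l_per_h: 90.0                # hepatic blood flow at reference BSA
  bsa_ref_m2: 1.90
  qh_bsa_exponent: 0.75
  qh_age_decline_per_y: 0.006         # fractional decline per year past onset
  qh_age_onset_y: 40.0
  liver_weight_coeff_g: 630.0         # liver weight = coeff * BSA^exponent * age factor
  liver_weight_bsa_exponent: 1.50
  liver_age_decline_per_y: 0.004
  liver_age_onset_y: 40.0
  liver_weight_ref_g: 1650.0
  mppgl_mg_per_g: {mean: 40.0, cv: 0.30, min: 20.0, max: 80.0}
  mppgl_ref_mg_per_g: 40.0
  enzyme_abundance:
    CYP3A4_hepatic: {mean: 93.0, cv: 0.50, min: 0.0001, max: 600.0}   # pmol/mg
    CYP2C8_hepatic: {mean: 22.4, cv: 0.60, min: 0.0001, max: 85.0}    # pmol/mg
    CYP3A4_gut:     {mean: 66.0, cv: 0.40, min: 5.0,    max: 250.0}   # nmol total
  cyp3a4_cyp2c8_rank_correlation: 0.68
  transporter_abundance:              # pmol / 1e6 hepatocytes
    P-gp:  {mean: 0.201, cv: 0.46, min: 0.02,  max: 1.0}
    BCRP:  {mean: 0.044, cv: 0.40, min: 0.005, max: 0.25}
  kdeg_per_h:
    CYP3A4_hepatic: 0.0158
    CYP2C8_hepatic: 0.0158
    CYP3A4_gut: 0.030
  egfr_ref_ml_min_173: 100.0
  serum_creatinine_umol_l:
    male_mean: 80.0
    female_mean: 65.0
    cv: 0.15
    age_slope_per_y: 0.003            # fractional rise per year past onset
    age_onset_y: 40.0
    min: 35.0
    max: 400.0
  aag_g_per_l:                        # healthy adults; males run slightly higher
    European: {male_mean: 0.95, female_mean: 0.87, cv: 0.18, min: 0.36, max: 1.46}
    Chinese:  {male_mean: 0.85, female_mean: 0.78, cv: 0.18, min: 0.36, max: 1.46}
    Japanese: {male_mean: 0.85, female_mean: 0.78, cv: 0.18, min: 0.36, max: 1.46}
  body_size:
    European:
      M: {weight_mean: 81.0, weight_sd: 13.0, height_mean: 176.0, height_sd: 7.0}
      F: {weight_mean: 66.0, weight_sd: 12.0, height_mean: 163.0, height_sd: 6.0}
    Chinese:
      M: {weight_mean: 68.0, weight_sd: 10.0, height_mean: 169.0, height_sd: 6.0}
      F: {weight_mean: 56.0, weight_sd: 8.0, height_mean: 157.0, height_sd: 5.0}
    Japanese:
      M: {weight_mean: 67.0, weight_sd: 10.0, height_mean: 168.0, height_sd: 6.0}
      F: {weight_mean: 54.0, weight_sd: 8.0, height_mean: 156.0, height_sd: 5.0}
  cirrhosis_multipliers:              # severity-graded, A < B < C
    A: {liver_weight: 0.95, qh: 0.92, cyp_abundance: 0.90, aag: 0.97}
    B: {liver_weight: 0.80, qh: 0.75, cyp_abundance: 0.65, aag: 0.90}
    C: {liver_weight: 0.65, qh: 0.60, cyp_abundance: 0.45, aag: 0.80}
  renal_multipliers:
    30to60: {aag: 1.30, cyp_abundance: 0.85, egfr_target: 45.0}
    lt30:   {aag: 1.50, cyp_abundance: 0.65, egfr_target: 25.0}

perpetrators:
  - name: diltiazem                   # moderate CYP3A4 inhibitor, 45 mg QID
    regimen: {dose_mg: 45.0, interval_h: 6.0, n_doses: 56, start_offset_h: 0.0}
    pk:
      molecular_weight_g_per_mol: 414.5
      ka_per_h: 1.0
      v_over_f_l: 300.0
      cl_over_f_l_per_h: 60.0
      fu: 0.22
      blood_plasma_ratio: 1.0
    metabolite: null
    interactions:                     # N-desmethyl metabolite folded into parent constants
      - enzyme: CYP3A4
        site: hepatic
        mechanism: mbi
        parameters: {KI_uM: 2.2, kinact_per_h: 0.50}
        acts_via: parent
      - enzyme: CYP3A4
        site: gut
        mechanism: mbi
        parameters: {KI_uM: 2.2, kinact_per_h: 0.50}
        acts_via: parent

  - name: verapamil                   # moderate CYP3A4 inhibitor, 60 mg TDS
    regimen: {dose_mg: 60.0, interval_h: 8.0, n_doses: 42, start_offset_h: 0.0}
    pk:
      molecular_weight_g_per_mol: 454.6
      ka_per_h: 1.0
      v_over_f_l: 600.0
      cl_over_f_l_per_h: 90.0
      fu: 0.10
      blood_plasma_ratio: 1.0
    metabolite: null
    interactions:                     # norverapamil folded into parent constants
      - enzyme: CYP3A4
        site: hepatic
        mechanism: mbi
        parameters: {KI_uM: 0.25, kinact_per_h: 0.33}
        acts_via: parent
      - enzyme: CYP3A4
        site: gut
        mechanism: mbi
        parameters: {KI_uM: 0.25, kinact_per_h: 0.33}
        acts_via: parent

  - name: trimethoprim                # weak CYP2C8 inhibitor, 300 mg daily days 8-14
    regimen: {dose_mg: 300.0, interval_h: 24.0, n_doses: 7, start_offset_h: 168.0}
    pk:
      molecular_weight_g_per_mol: 290.3
      ka_per_h: 1.5
      v_over_f_l: 110.0
      cl_over_f_l_per_h: 5.5
      fu: 0.5
      blood_plasma_ratio: 1.0
    metabolite: null
    interactions:
      - enzyme: CYP2C8
        site: hepatic
        mechanism: competitive
        parameters: {ki_uM: 3.2}
        acts_via: parent

  - name: clopidogrel                 # CYP2C8 inactivation via the acyl glucuronide
    regimen: {dose_mg: 75.0, interval_h: 24.0, n_doses: 14, start_offset_h: 0.0}
    pk:
      molecular_weight_g_per_mol: 321.8
      ka_per_h: 2.0
      v_over_f_l: 200.0
      cl_over_f_l_per_h: 23.0
      fu: 0.02
      blood_plasma_ratio: 1.0
    metabolite:
      name: clopidogrel acyl glucuronide
      fraction_formed: 0.5
      molecular_weight_g_per_mol: 497.9
      v_l: 60.0
      ke_per_h: 0.10
      fu: 0.16
    interactions:
      - enzyme: CYP2C8
        site: hepatic
        mechanism: mbi
        parameters: {KI_uM: 9.9, kinact_per_h: 2.82}
        acts_via: metabolite

  - name: hyperforin                  # St John's Wort constituent, gut CYP3A4 inducer only
    regimen: {dose_mg: 45.0, interval_h: 24.0, n_doses: 14, start_offset_h: 0.0}
    pk:
      molecular_weight_g_per_mol: 536.8
      ka_per_h: 0.5
      v_over_f_l: 300.0
      cl_over_f_l_per_h: 20.0
      fu: 0.01
      blood_plasma_ratio: 1.0
    metabolite: null
    interactions:
      - enzyme: CYP3A4
        site: gut
        mechanism: induction
        parameters: {ind_max: 8.6, ind_c50_uM: 0.012}
        acts_via: parent
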