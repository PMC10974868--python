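# In-vitro GIS scenario for the VALS_BE/HCTZ_Low test product (generic
# candidate that was bioequivalent for valsartan).
name: VALS_BE/HCTZ_Low
mode: in_vitro
provenance: >-
  Published fasted-state GIS operating conditions and the in-vitro
  curve-fitted z-factor/precipitation coefficients for the first test product.
gis:
  dose_mg: 320.0
  ksec_s_mL_min: 1.0
  ksec_d_mL_min: 1.0
  t_half_G_min: 8.0
  Vs0_mL: 300.0
  Vs_min_mL: 10.0
  Vd_mL: 50.0
  Vj0_mL: 0.0
  t_end_min: 240.0
  Cs_mg_mL:
    stomach: 0.08
    duodenum: 9.21
    jejunum: 9.21
  gastric_acid:             # dosing medium: 50 mL 0.01 M SGF + 250 mL water;
    secretion_conc_mmol_mL: 0.01   # secreted SGF acidity
    initial_mmol: 0.5              # 0.01 M x 50 mL in the dosed medium
    solubility_ph_anchors: {2.0: 0.08, 4.5: 1.23, 6.8: 9.21}
formulation:
  Zs_mL_mg_min: 3.26e-5
  Zd_mL_mg_min: 1.94e-4
  Zj_mL_mg_min: 3.75e-9
  kpre_s_per_min: 2.41e-3
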