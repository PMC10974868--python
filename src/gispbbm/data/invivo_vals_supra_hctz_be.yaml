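# In-vivo PBBM scenario for the VALS_Supra/HCTZ_BE test product (fast
# disintegration: large gastric z-factor; less sorbitol, so reference-like
# gastric emptying and transit window).
name: VALS_Supra/HCTZ_BE
mode: in_vivo
provenance: >-
  Published final PBBM parameter set for the second test product;
  coefficients scaled from the in-vitro fits (x4 Zs/Zd, x10 Zj, x0.2
  kpre_s), rat permeability scaled x4.
gis:
  dose_mg: 320.0
  ksec_s_mL_min: 1.0
  ksec_d_mL_min: 1.0
  t_half_G_min: 13.0
  Vs0_mL: 300.0
  Vs_min_mL: 5.0
  Vd_mL: 50.0
  Vj0_mL: 0.0
  t_end_min: 2880.0
  Cs_mg_mL:
    stomach: 0.08
    duodenum: 9.21
    jejunum: 9.21
  gastric_acid:             # dosing medium: 50 mL 0.01 M SGF + 250 mL water;
    secretion_conc_mmol_mL: 0.01   # secreted SGF acidity
    initial_mmol: 0.5              # 0.01 M x 50 mL in the dosed medium
    solubility_ph_anchors: {2.0: 0.08, 4.5: 1.23, 6.8: 9.21}
formulation:
  Zs_mL_mg_min: 1.15
  Zd_mL_mg_min: 1.15e-3
  Zj_mL_mg_min: 2.30e-12
  kpre_s_per_min: 1.18e-7
  Peff_cm_min: 59.5e-4
  t_half_G_min: 13.0
  tcut_min: 600.0
  R_cm: 1.5
  kt_per_min: 0.0056
pk:
  Vc_over_Fsys_mL: 25120.7
  k10_per_h: 0.26753
  k12_per_h: 0.06743
  k21_per_h: 0.05925
  Fsys: 0.39
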