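# In-vivo PBBM scenario for the VALS_BE/HCTZ_Low test product.  Its higher
# sorbitol content slows gastric emptying (15 min half-life) and shortens the
# intestinal absorption window (tcut 360 min).
name: VALS_BE/HCTZ_Low
mode: in_vivo
provenance: >-
  Published final PBBM parameter set for the first test product; coefficients
  scaled from the in-vitro fits (x4 Zs/Zd, x10 Zj, x0.2 kpre_s), rat
  permeability scaled x4.
gis:
  dose_mg: 320.0
  ksec_s_mL_min: 1.0
  ksec_d_mL_min: 1.0
  t_half_G_min: 15.0
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
  Zs_mL_mg_min: 1.30e-4
  Zd_mL_mg_min: 7.76e-4
  Zj_mL_mg_min: 3.75e-8
  kpre_s_per_min: 4.82e-4
  Peff_cm_min: 47.0e-4
  t_half_G_min: 15.0
  tcut_min: 360.0
  R_cm: 1.5
  kt_per_min: 0.0056
pk:
  Vc_over_Fsys_mL: 25120.7
  k10_per_h: 0.26753
  k12_per_h: 0.06743
  k21_per_h: 0.05925
  Fsys: 0.39
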