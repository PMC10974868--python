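# In-vivo PBBM scenario for the valsartan reference product (Co-Diovan
# Forte): final published model parameters (scaled dissolution/precipitation
# coefficients, human permeability scaled from rat perfusion, formulation
# gastric half-life and absorption-window cutoff) plus disposition constants.
name: CoDiovan
mode: in_vivo
provenance: >-
  Published final PBBM parameter set for the reference product; dissolution
  and precipitation coefficients are the in-vitro fits scaled x4 (Zs, Zd),
  x10 (Zj) and x0.2 (kpre_s); Peff is the rat perfusion value scaled x4.
gis:
  dose_mg: 320.0
  ksec_s_mL_min: 1.0
  ksec_d_mL_min: 1.0
  t_half_G_min: 13.0        # overridden identically by the formulation block
  Vs0_mL: 300.0
  Vs_min_mL: 5.0            # in-vivo gastric volume floor
  Vd_mL: 50.0
  Vj0_mL: 0.0
  t_end_min: 2880.0         # 48 h sampling window
  Cs_mg_mL:
    stomach: 0.08
    duodenum: 9.21
    jejunum: 9.21
  gastric_acid:             # dosing medium: 50 mL 0.01 M SGF + 250 mL water;
    secretion_conc_mmol_mL: 0.01   # secreted SGF acidity
    initial_mmol: 0.5              # 0.01 M x 50 mL in the dosed medium
    solubility_ph_anchors: {2.0: 0.08, 4.5: 1.23, 6.8: 9.21}
formulation:
  Zs_mL_mg_min: 9.68e-5     # scaled from the in-vitro coefficient (x4)
  Zd_mL_mg_min: 9.40e-4     # scaled (x4)
  Zj_mL_mg_min: 4.20e-9     # scaled (x10)
  kpre_s_per_min: 3.98e-4   # scaled (x0.2)
  Peff_cm_min: 41.6e-4      # rat value scaled to human (x4)
  t_half_G_min: 13.0        # gastric emptying half-life for this product
  tcut_min: 600.0           # total transit time in the absorption window
  R_cm: 1.5                 # human intestinal radius
  kt_per_min: 0.0056        # jejunum -> distal transit constant
pk:
  Vc_over_Fsys_mL: 25120.7
  k10_per_h: 0.26753
  k12_per_h: 0.06743
  k21_per_h: 0.05925
  Fsys: 0.39
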