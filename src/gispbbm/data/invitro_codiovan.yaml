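# Fasted-state transfer-dissolution (GIS) scenario for the valsartan 320 mg
# reference product (Co-Diovan Forte): published device configuration and
# curve-fitted in-vitro dissolution/precipitation coefficients.
name: CoDiovan
mode: in_vitro
provenance: >-
  Published fasted-state GIS operating conditions (volumes, secretion rates,
  gastric half-life, valsartan solubilities) and the in-vitro curve-fitted
  z-factor/precipitation coefficients for the reference product.
gis:
  dose_mg: 320.0            # valsartan content of one tablet
  ksec_s_mL_min: 1.0        # simulated gastric fluid secretion
  ksec_d_mL_min: 1.0        # pH 6.8 phosphate buffer secretion
  t_half_G_min: 8.0         # first-order gastric emptying half-life (device setting)
  Vs0_mL: 300.0             # 50 mL SGF + 250 mL water
  Vs_min_mL: 10.0           # device floor on the gastric volume
  Vd_mL: 50.0               # constant duodenal volume
  Vj0_mL: 0.0               # empty accumulative jejunal receiver
  t_end_min: 240.0
  Cs_mg_mL:                 # valsartan saturation solubility per chamber medium
    stomach: 0.08           # pH 2.0
    duodenum: 9.21          # pH 6.8
    jejunum: 9.21           # pH 6.8
  gastric_acid:             # dosing medium: 50 mL 0.01 M SGF + 250 mL water;
    secretion_conc_mmol_mL: 0.01   # secreted SGF acidity
    initial_mmol: 0.5              # 0.01 M x 50 mL in the dosed medium
    solubility_ph_anchors: {2.0: 0.08, 4.5: 1.23, 6.8: 9.21}
formulation:
  Zs_mL_mg_min: 2.42e-5
  Zd_mL_mg_min: 2.35e-4
  Zj_mL_mg_min: 4.20e-10
  kpre_s_per_min: 1.99e-3
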