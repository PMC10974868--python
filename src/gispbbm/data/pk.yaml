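# Two-compartment disposition parameters of valsartan, fitted to the oral
# plasma profiles of the reference product (rate constants per hour, as
# reported; the package converts to per-minute internally).
pk:
  Vc_over_Fsys_mL: 25120.7   # apparent central volume Vc/Fsys
  k10_per_h: 0.26753         # first-order elimination from the central compartment
  k12_per_h: 0.06743         # central -> peripheral distribution
  k21_per_h: 0.05925         # peripheral -> central distribution
  Fsys: 0.39                 # systemic availability (fraction absorbed x first-pass survival)
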