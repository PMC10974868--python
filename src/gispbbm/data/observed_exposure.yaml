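# Observed exposure metrics of valsartan from the two crossover
# bioequivalence studies (non-compartmental analysis of the clinical plasma
# profiles), used as the comparison column for prediction errors.
# Cmax in mg/mL; AUC0-t in mg/mL*min.
experimental:
  CoDiovan:            {Cmax_mg_mL: 5.73e-3, AUC0t_mg_mL_min: 2.93}
  VALS_BE/HCTZ_Low:    {Cmax_mg_mL: 5.93e-3, AUC0t_mg_mL_min: 3.03}
  VALS_Supra/HCTZ_BE:  {Cmax_mg_mL: 6.70e-3, AUC0t_mg_mL_min: 3.17}
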