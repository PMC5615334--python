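# Per-organ model parameters for Hodgkin-lymphoma / childhood-cancer
# survivor cohorts.  Keys match OrganParams field names.
# lam: per day | alpha_R, gamma_R: per Gy | alpha_C, gamma_C: per (mg/m^2)
# alpha_d: per day | r, g: dimensionless | N: cells
breast:
  organ: breast
  lam: 0.4
  r: 0.76
  N: 1.0e+6
  alpha_R: 0.18
  gamma_R: 1.0e-6
  alpha_C: 0.2
  gamma_C: 1.0e-9
  alpha_d: 0.1333
  g: 1.2
lung:
  organ: lung
  lam: 0.4
  r: 0.96
  N: 1.0e+6
  alpha_R: 0.18
  gamma_R: 1.0e-6
  alpha_C: 0.2
  gamma_C: 0.5e-6
  alpha_d: 0.1333
  g: 0.18
thyroid:
  organ: thyroid
  lam: 0.4
  r: 0.68
  N: 1.0e+6
  alpha_R: 0.25
  gamma_R: 1.0e-6
  alpha_C: 0.2
  gamma_C: 0.9e-7
  alpha_d: 0.1333
  g: 1.0
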