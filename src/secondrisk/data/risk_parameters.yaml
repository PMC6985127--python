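# Default organ parameter registry for OED / EAR calculation.
#
# Dose-response coefficients (alpha_prime in Gy^-1, R dimensionless) are from
# combined fits to atomic-bomb survivor data and Hodgkin patients treated at
# 2-40 Gy, assuming alpha/beta = 3 Gy (fraction-size effects are folded into
# alpha_prime; apply to total accumulated dose per bin).
#
# EAR population parameters (beta_prime in cases per 10,000 person-years per
# Gy; gamma_e per year of age at exposure; gamma_a on ln(attained age/70))
# are Schneider-style site-specific defaults for breast and lung.  They are
# a documented, editable choice: absolute EAR values depend on them directly.
#
# Organ labels: CB = contralateral breast, CL = contralateral lung,
# IL = ipsilateral lung.

CB:
  site: breast
  linear_exponential: {alpha_prime: 0.041}
  plateau: {alpha_prime: 0.115}
  mechanistic: {alpha_prime: 0.044, R: 0.15}
  ear: {beta_prime: 8.2, gamma_e: -0.037, gamma_a: 1.7}

CL:
  site: lung
  linear_exponential: {alpha_prime: 0.022}
  plateau: {alpha_prime: 0.056}
  mechanistic: {alpha_prime: 0.042, R: 0.83}
  ear: {beta_prime: 8.0, gamma_e: 0.002, gamma_a: 4.23}

IL:
  site: lung
  linear_exponential: {alpha_prime: 0.022}
  plateau: {alpha_prime: 0.056}
  mechanistic: {alpha_prime: 0.042, R: 0.83}
  ear: {beta_prime: 8.0, gamma_e: 0.002, gamma_a: 4.23}
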