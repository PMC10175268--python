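n_mdd: 88
n_hc: 50
rho_mdd: 0.2
rho_hc: 0.2
psi_pet: 0.02
psi_fmri: 0.28
pet_loadings:
  putamen: 1.0
  caudate: 1.84
  amygdala: 1.25
  insula: 1.4
  vmpfc: 1.6
  dlpfc: 1.1
fmri_loadings:
  amygdala: 1.0
  insula: 0.8
  vmpfc: 0.36
  dlpfc: 0.55
pet_intercepts:
  putamen: 1.2
  caudate: 1.25
  amygdala: 0.6
  insula: 0.2
  vmpfc: 0.1
  dlpfc: 0.0
fmri_intercepts:
  amygdala: 0.4
  insula: 0.35
  vmpfc: 0.2
  dlpfc: 0.3
pet_resid_var:
  putamen: 0.01
  caudate: 0.02
  amygdala: 0.02
  insula: 0.012
  vmpfc: 0.015
  dlpfc: 0.012
fmri_resid_var:
  amygdala: 0.3
  insula: 0.25
  vmpfc: 0.35
  dlpfc: 0.3
caudate_putamen_resid_corr: 0.3
mdd_pet_shift: -0.05
mdd_fmri_shift: 0.0
beta_age_pet: -0.0005
beta_sex_pet: 0.004
beta_genotype_pet: -0.004
beta_injmass_pet: -0.1
beta_age_fmri: -0.002
beta_sex_fmri: 0.02
age_mean: 26.0
age_sd: 7.0
female_p_mdd: 0.7045454545454546
female_p_hc: 0.92
carrier_p: 0.72
inj_mass_mean_mdd: 0.013
inj_mass_sd_mdd: 0.014
inj_mass_mean_hc: 0.015
inj_mass_sd_hc: 0.016
inj_mass_ref: 0.014
seed: 0
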