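latents:
- name: PET_LV
  indicators:
  - pet_putamen
  - pet_caudate
  - pet_amygdala
  - pet_insula
  - pet_vmpfc
  - pet_dlpfc
  reference: pet_putamen
- name: fMRI_LV
  indicators:
  - fmri_amygdala
  - fmri_insula
  - fmri_vmpfc
  - fmri_dlpfc
  reference: fmri_amygdala
loadings:
- indicator: pet_putamen
  latent: PET_LV
  param: lam_pet_putamen
- indicator: pet_caudate
  latent: PET_LV
  param: lam_PET_LV
- indicator: pet_amygdala
  latent: PET_LV
  param: lam_PET_LV
- indicator: pet_insula
  latent: PET_LV
  param: lam_PET_LV
- indicator: pet_vmpfc
  latent: PET_LV
  param: lam_PET_LV
- indicator: pet_dlpfc
  latent: PET_LV
  param: lam_PET_LV
- indicator: fmri_amygdala
  latent: fMRI_LV
  param: lam_fmri_amygdala
- indicator: fmri_insula
  latent: fMRI_LV
  param: lam_fMRI_LV
- indicator: fmri_vmpfc
  latent: fMRI_LV
  param: lam_fMRI_LV
- indicator: fmri_dlpfc
  latent: fMRI_LV
  param: lam_fMRI_LV
intercepts:
  pet_putamen: nu_pet_putamen
  pet_caudate: nu_pet_caudate
  pet_amygdala: nu_pet_amygdala
  pet_insula: nu_pet_insula
  pet_vmpfc: nu_pet_vmpfc
  pet_dlpfc: nu_pet_dlpfc
  fmri_amygdala: nu_fmri_amygdala
  fmri_insula: nu_fmri_insula
  fmri_vmpfc: nu_fmri_vmpfc
  fmri_dlpfc: nu_fmri_dlpfc
latent_means:
  PET_LV: alpha_PET_LV|HC
  fMRI_LV: alpha_fMRI_LV|HC
covariate_paths:
- - age
  - pet_putamen
  - g_age_pet_putamen
- - age
  - pet_caudate
  - g_age_pet_caudate
- - age
  - pet_amygdala
  - g_age_pet_amygdala
- - age
  - pet_insula
  - g_age_pet_insula
- - age
  - pet_vmpfc
  - g_age_pet_vmpfc
- - age
  - pet_dlpfc
  - g_age_pet_dlpfc
- - age
  - fmri_amygdala
  - g_age_fmri_amygdala
- - age
  - fmri_insula
  - g_age_fmri_insula
- - age
  - fmri_vmpfc
  - g_age_fmri_vmpfc
- - age
  - fmri_dlpfc
  - g_age_fmri_dlpfc
- - sex
  - pet_putamen
  - g_sex_pet_putamen
- - sex
  - pet_caudate
  - g_sex_pet_caudate
- - sex
  - pet_amygdala
  - g_sex_pet_amygdala
- - sex
  - pet_insula
  - g_sex_pet_insula
- - sex
  - pet_vmpfc
  - g_sex_pet_vmpfc
- - sex
  - pet_dlpfc
  - g_sex_pet_dlpfc
- - sex
  - fmri_amygdala
  - g_sex_fmri_amygdala
- - sex
  - fmri_insula
  - g_sex_fmri_insula
- - sex
  - fmri_vmpfc
  - g_sex_fmri_vmpfc
- - sex
  - fmri_dlpfc
  - g_sex_fmri_dlpfc
- - genotype
  - pet_putamen
  - g_genotype_pet_putamen
- - genotype
  - pet_caudate
  - g_genotype_pet_caudate
- - genotype
  - pet_amygdala
  - g_genotype_pet_amygdala
- - genotype
  - pet_insula
  - g_genotype_pet_insula
- - genotype
  - pet_vmpfc
  - g_genotype_pet_vmpfc
- - genotype
  - pet_dlpfc
  - g_genotype_pet_dlpfc
- - inj_mass
  - pet_putamen
  - g_inj_mass_pet_putamen
- - inj_mass
  - pet_caudate
  - g_inj_mass_pet_caudate
- - inj_mass
  - pet_amygdala
  - g_inj_mass_pet_amygdala
- - inj_mass
  - pet_insula
  - g_inj_mass_pet_insula
- - inj_mass
  - pet_vmpfc
  - g_inj_mass_pet_vmpfc
- - inj_mass
  - pet_dlpfc
  - g_inj_mass_pet_dlpfc
latent_cov:
- row: PET_LV
  col: PET_LV
  param: psi_PET_LV|HC
- row: fMRI_LV
  col: fMRI_LV
  param: psi_fMRI_LV|HC
- row: PET_LV
  col: fMRI_LV
  param: psi_PET_LV_fMRI_LV|HC
residual_cov:
- row: pet_putamen
  col: pet_putamen
  param: theta_pet_putamen
- row: pet_caudate
  col: pet_caudate
  param: theta_pet_caudate
- row: pet_amygdala
  col: pet_amygdala
  param: theta_pet_amygdala
- row: pet_insula
  col: pet_insula
  param: theta_pet_insula
- row: pet_vmpfc
  col: pet_vmpfc
  param: theta_pet_vmpfc
- row: pet_dlpfc
  col: pet_dlpfc
  param: theta_pet_dlpfc
- row: fmri_amygdala
  col: fmri_amygdala
  param: theta_fmri_amygdala
- row: fmri_insula
  col: fmri_insula
  param: theta_fmri_insula
- row: fmri_vmpfc
  col: fmri_vmpfc
  param: theta_fmri_vmpfc
- row: fmri_dlpfc
  col: fmri_dlpfc
  param: theta_fmri_dlpfc
constraints: []
fixed:
  lam_pet_putamen: 1.0
  lam_fmri_amygdala: 1.0
  alpha_PET_LV|HC: 0.0
  alpha_fMRI_LV|HC: 0.0
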