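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
  param: lam_pet_caudate
- indicator: pet_amygdala
  latent: PET_LV
  param: lam_pet_amygdala
- indicator: pet_insula
  latent: PET_LV
  param: lam_pet_insula
- indicator: pet_vmpfc
  latent: PET_LV
  param: lam_pet_vmpfc
- indicator: pet_dlpfc
  latent: PET_LV
  param: lam_pet_dlpfc
- indicator: fmri_amygdala
  latent: fMRI_LV
  param: lam_fmri_amygdala
- indicator: fmri_insula
  latent: fMRI_LV
  param: lam_fmri_insula
- indicator: fmri_vmpfc
  latent: fMRI_LV
  param: lam_fmri_vmpfc
- indicator: fmri_dlpfc
  latent: fMRI_LV
  param: lam_fmri_dlpfc
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
  PET_LV: alpha_PET_LV
  fMRI_LV: alpha_fMRI_LV
covariate_paths:
- - age
  - PET_LV
  - b_age_PET_LV
- - age
  - fMRI_LV
  - b_age_fMRI_LV
- - sex
  - PET_LV
  - b_sex_PET_LV
- - sex
  - fMRI_LV
  - b_sex_fMRI_LV
- - genotype
  - PET_LV
  - b_genotype_PET_LV
- - inj_mass
  - PET_LV
  - b_inj_mass_PET_LV
latent_cov:
- row: PET_LV
  col: PET_LV
  param: psi_PET_LV
- row: fMRI_LV
  col: fMRI_LV
  param: psi_fMRI_LV
- row: PET_LV
  col: fMRI_LV
  param: psi_PET_LV_fMRI_LV
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
  alpha_PET_LV: 0.0
  alpha_fMRI_LV: 0.0
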