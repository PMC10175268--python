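"""Synthetic subject-level cohorts with the latent structure the analysis assumes.

The generator emulates a PET/fMRI cohort of 88 MDD patients and 50 healthy
controls: per subject it draws covariates (age, sex, 5-HTTLPR class,
injected tracer mass), a bivariate-normal latent pair (PET_LV on the log
BP_ND scale, fMRI_LV on the contrast scale) with configurable per-group
correlation, a group shift on the PET latent mean, and regional indicators
``nu + lambda * eta + eps``.  PET noise is added on the log scale and the
stored BP_ND is the exponential, so the log-linear model fitted downstream
is exactly correctly specified and the positivity invariant holds for every
seed.  A caudate-putamen residual correlation can be injected to give the
model search a true path to find.

Everything is driven by a :class:`SimulationConfig`; the same config and
seed reproduce the table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lvm_spec import (
    FMRI_ROIS,
    GROUPS,
    PET_ROIS,
    CohortTable,
    SpecError,
    fmri_col,
    pet_col,
)

__all__ = ["SimulationConfig", "generate_cohort", "oracle_moments", "truth_parameters"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for a synthetic cohort.

    Latent variances are on the modelled scales (log BP_ND for PET_LV,
    contrast units for fMRI_LV); their defaults put the latent covariance at
    rho * sqrt(psi_pet * psi_fmri) ~= 0.015 when rho = 0.20.  Loadings sit
    inside the ranges the fitted models typically produce (PET 1.00-1.84,
    fMRI 0.36-1.00, reference loadings fixed at 1).  Covariate effects
    default to near zero; sex frequencies per group, the 5-HTTLPR carrier
    frequency and the per-group injected-mass distributions follow the
    cohort composition the generator emulates.
    """

    n_mdd: int = 88
    n_hc: int = 50
    rho_mdd: float = 0.20
    rho_hc: float = 0.20
    psi_pet: float = 0.02
    psi_fmri: float = 0.28
    pet_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "putamen": 1.0,
            "caudate": 1.84,
            "amygdala": 1.25,
            "insula": 1.4,
            "vmpfc": 1.6,
            "dlpfc": 1.1,
        }
    )
    fmri_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "amygdala": 1.0,
            "insula": 0.8,
            "vmpfc": 0.36,
            "dlpfc": 0.55,
        }
    )
    pet_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "putamen": 1.20,
            "caudate": 1.25,
            "amygdala": 0.60,
            "insula": 0.20,
            "vmpfc": 0.10,
            "dlpfc": 0.00,
        }
    )
    fmri_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "amygdala": 0.40,
            "insula": 0.35,
            "vmpfc": 0.20,
            "dlpfc": 0.30,
        }
    )
    pet_resid_var: dict[str, float] = field(
        default_factory=lambda: {
            "putamen": 0.010,
            "caudate": 0.020,
            "amygdala": 0.020,
            "insula": 0.012,
            "vmpfc": 0.015,
            "dlpfc": 0.012,
        }
    )
    fmri_resid_var: dict[str, float] = field(
        default_factory=lambda: {
            "amygdala": 0.30,
            "insula": 0.25,
            "vmpfc": 0.35,
            "dlpfc": 0.30,
        }
    )
    caudate_putamen_resid_corr: float = 0.3
    mdd_pet_shift: float = -0.05  # MDD latent-mean shift, log BP_ND units
    mdd_fmri_shift: float = 0.0
    # near-zero covariate effects on the latents (study-scale defaults)
    beta_age_pet: float = -0.0005
    beta_sex_pet: float = 0.004
    beta_genotype_pet: float = -0.004
    beta_injmass_pet: float = -0.10
    beta_age_fmri: float = -0.002
    beta_sex_fmri: float = 0.02
    # covariate distributions
    age_mean: float = 26.0
    age_sd: float = 7.0
    female_p_mdd: float = 62 / 88
    female_p_hc: float = 46 / 50
    carrier_p: float = 0.72  # S' carrier frequency (1 - 0.28 LA/LA)
    inj_mass_mean_mdd: float = 0.013
    inj_mass_sd_mdd: float = 0.014
    inj_mass_mean_hc: float = 0.015
    inj_mass_sd_hc: float = 0.016
    inj_mass_ref: float = 0.014  # centering point for the injected-mass effect
    seed: int = 0

    def __post_init__(self):
        if self.n_mdd < 1 or self.n_hc < 1:
            raise SpecError("need at least one subject per group")
        for rho in (self.rho_mdd, self.rho_hc):
            if not -1 < rho < 1:
                raise SpecError("latent correlation must be in (-1, 1)")
        for name in ("psi_pet", "psi_fmri", "age_sd"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        for d in (self.pet_resid_var, self.fmri_resid_var):
            if any(v <= 0 for v in d.values()):
                raise SpecError("residual variances must be positive")
        if not -1 < self.caudate_putamen_resid_corr < 1:
            raise SpecError("residual correlation must be in (-1, 1)")
        if set(self.pet_loadings) != set(PET_ROIS) or set(self.fmri_loadings) != set(
            FMRI_ROIS
        ):
            raise SpecError("loadings must cover exactly the configured ROIs")

    # Convenience variants -----------------------------------------------
    def homogeneous(self, **overrides) -> "SimulationConfig":
        """No group shift and equal correlations: the common (group-free)
        model is then exactly correctly specified — used for parameter
        recovery and null calibration."""
        base = dict(mdd_pet_shift=0.0, mdd_fmri_shift=0.0, rho_hc=self.rho_mdd)
        base.update(overrides)
        return replace(self, **base)

    def equal_loadings(self, pet: float = 1.3, fmri: float = 0.7, **overrides):
        """All non-reference loadings equal within each latent, so the
        constrained group model is exactly correctly specified."""
        pet_l = {roi: (1.0 if roi == PET_ROIS[0] else pet) for roi in PET_ROIS}
        fmri_l = {roi: (1.0 if roi == FMRI_ROIS[0] else fmri) for roi in FMRI_ROIS}
        return replace(self, pet_loadings=pet_l, fmri_loadings=fmri_l, **overrides)

    # Derived truth ------------------------------------------------------
    def psi(self, group: str) -> np.ndarray:
        rho = {"MDD": self.rho_mdd, "HC": self.rho_hc}[group]
        cov = rho * np.sqrt(self.psi_pet * self.psi_fmri)
        return np.array([[self.psi_pet, cov], [cov, self.psi_fmri]])

    def latent_shift(self, group: str) -> np.ndarray:
        if group == "MDD":
            return np.array([self.mdd_pet_shift, self.mdd_fmri_shift])
        return np.zeros(2)

    def theta_matrix(self) -> np.ndarray:
        """Residual covariance over (log-PET, fMRI) indicators."""
        var = [self.pet_resid_var[r] for r in PET_ROIS] + [
            self.fmri_resid_var[r] for r in FMRI_ROIS
        ]
        Theta = np.diag(var)
        i = list(PET_ROIS).index("putamen")
        j = list(PET_ROIS).index("caudate")
        cov = self.caudate_putamen_resid_corr * np.sqrt(
            self.pet_resid_var["putamen"] * self.pet_resid_var["caudate"]
        )
        Theta[i, j] = Theta[j, i] = cov
        return Theta

    def lambda_matrix(self) -> np.ndarray:
        p = len(PET_ROIS) + len(FMRI_ROIS)
        Lam = np.zeros((p, 2))
        for k, roi in enumerate(PET_ROIS):
            Lam[k, 0] = self.pet_loadings[roi]
        for k, roi in enumerate(FMRI_ROIS):
            Lam[len(PET_ROIS) + k, 1] = self.fmri_loadings[roi]
        return Lam

    def nu_vector(self) -> np.ndarray:
        return np.array(
            [self.pet_intercepts[r] for r in PET_ROIS]
            + [self.fmri_intercepts[r] for r in FMRI_ROIS]
        )

    # Serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CohortTable, dict[str, float]]:
    """Draw one cohort; returns the table and the exact generative truth.

    The truth record maps common-model parameter names to the values used
    (see :func:`truth_parameters`).  ``seed`` overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    Lam = config.lambda_matrix()
    Theta = config.theta_matrix()
    L_theta = np.linalg.cholesky(Theta)
    nu = config.nu_vector()
    n_pet = len(PET_ROIS)

    frames = []
    for group, n in (("MDD", config.n_mdd), ("HC", config.n_hc)):
        age = rng.normal(config.age_mean, config.age_sd, size=n)
        female_p = config.female_p_mdd if group == "MDD" else config.female_p_hc
        sex = rng.binomial(1, female_p, size=n).astype(float)
        genotype = rng.binomial(1, config.carrier_p, size=n).astype(float)
        if group == "MDD":
            mu_im, sd_im = config.inj_mass_mean_mdd, config.inj_mass_sd_mdd
        else:
            mu_im, sd_im = config.inj_mass_mean_hc, config.inj_mass_sd_hc
        m, s = _lognormal_params(mu_im, sd_im)
        inj = rng.lognormal(m, s, size=n)

        eta_mean = np.tile(config.latent_shift(group), (n, 1))
        eta_mean[:, 0] += (
            config.beta_age_pet * (age - config.age_mean)
            + config.beta_sex_pet * sex
            + config.beta_genotype_pet * genotype
            + config.beta_injmass_pet * (inj - config.inj_mass_ref)
        )
        eta_mean[:, 1] += config.beta_age_fmri * (age - config.age_mean) + (
            config.beta_sex_fmri * sex
        )
        L_psi = np.linalg.cholesky(config.psi(group))
        eta = eta_mean + rng.standard_normal((n, 2)) @ L_psi.T
        eps = rng.standard_normal((n, Theta.shape[0])) @ L_theta.T
        Y = nu[None, :] + eta @ Lam.T + eps  # log-PET block, raw fMRI block
        data = {
            "id": [f"{group}{k:04d}" for k in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "genotype": genotype,
            "inj_mass": inj,
        }
        for k, roi in enumerate(PET_ROIS):
            data[pet_col(roi)] = np.exp(Y[:, k])  # stored as BP_ND > 0
        for k, roi in enumerate(FMRI_ROIS):
            data[fmri_col(roi)] = Y[:, n_pet + k]
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True)
    return CohortTable(df), truth_parameters(config)


def truth_parameters(config: SimulationConfig) -> dict[str, float]:
    """Generative truth keyed by common-model parameter names.

    The common-model keys describe the pooled structure exactly when the
    config is homogeneous (no group shift, equal correlations); group-keyed
    psi and latent-mean entries are appended with a ``|group`` suffix.
    """
    out: dict[str, float] = {}
    for roi in PET_ROIS:
        out[f"lam_{pet_col(roi)}"] = config.pet_loadings[roi]
        out[f"nu_{pet_col(roi)}"] = config.pet_intercepts[roi]
        out[f"theta_{pet_col(roi)}"] = config.pet_resid_var[roi]
    for roi in FMRI_ROIS:
        out[f"lam_{fmri_col(roi)}"] = config.fmri_loadings[roi]
        out[f"nu_{fmri_col(roi)}"] = config.fmri_intercepts[roi]
        out[f"theta_{fmri_col(roi)}"] = config.fmri_resid_var[roi]
    Psi = config.psi("MDD")
    out["psi_PET_LV"] = config.psi_pet
    out["psi_fMRI_LV"] = config.psi_fmri
    out["psi_PET_LV_fMRI_LV"] = float(Psi[0, 1])
    pair = (pet_col("putamen"), pet_col("caudate"))
    out[f"theta_{pair[0]}_{pair[1]}"] = float(config.theta_matrix()[0, 1])
    out["b_age_PET_LV"] = config.beta_age_pet
    out["b_sex_PET_LV"] = config.beta_sex_pet
    out["b_genotype_PET_LV"] = config.beta_genotype_pet
    out["b_inj_mass_PET_LV"] = config.beta_injmass_pet
    out["b_age_fMRI_LV"] = config.beta_age_fmri
    out["b_sex_fMRI_LV"] = config.beta_sex_fmri
    for g in GROUPS:
        Psi_g = config.psi(g)
        shift = config.latent_shift(g)
        out[f"psi_PET_LV|{g}"] = float(Psi_g[0, 0])
        out[f"psi_fMRI_LV|{g}"] = float(Psi_g[1, 1])
        out[f"psi_PET_LV_fMRI_LV|{g}"] = float(Psi_g[0, 1])
        out[f"alpha_PET_LV|{g}"] = float(shift[0])
        out[f"alpha_fMRI_LV|{g}"] = float(shift[1])
    return out


def oracle_moments(
    config: SimulationConfig,
    group: str = "MDD",
    x: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form population moments of the modelled vector (log-PET, fMRI)
    conditional on covariates, built directly from the config arrays.

    ``x`` defaults to the reference covariate point (age at its mean, sex
    and genotype 0, injected mass at its centering value).  Must agree with
    :func:`petbold.lvm_spec.implied_moments` at the generative parameters.
    """
    if group not in GROUPS:
        raise SpecError(f"unknown group {group!r}")
    if x is None:
        x = {"age": config.age_mean, "sex": 0.0, "genotype": 0.0,
             "inj_mass": config.inj_mass_ref}
    eta_mean = config.latent_shift(group).astype(float).copy()
    eta_mean[0] += (
        config.beta_age_pet * (x["age"] - config.age_mean)
        + config.beta_sex_pet * x["sex"]
        + config.beta_genotype_pet * x["genotype"]
        + config.beta_injmass_pet * (x["inj_mass"] - config.inj_mass_ref)
    )
    eta_mean[1] += config.beta_age_fmri * (x["age"] - config.age_mean) + (
        config.beta_sex_fmri * x["sex"]
    )
    Lam = config.lambda_matrix()
    mu = config.nu_vector() + Lam @ eta_mean
    Sigma = Lam @ config.psi(group) @ Lam.T + config.theta_matrix()
    return mu, (Sigma + Sigma.T) / 2.0
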