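"""Shared fixtures: small cohorts and toy model specs."""

import numpy as np
import pandas as pd
import pytest

from petbold import (
    FitOptions,
    LatentDef,
    ModelSpec,
    SimulationConfig,
    generate_cohort,
)


def single_latent_spec(n_ind: int = 3, covariates: bool = False) -> ModelSpec:
    """One latent with ``n_ind`` indicators, reference loading fixed at 1."""
    inds = tuple(f"y{k}" for k in range(1, n_ind + 1))
    loadings = {(ind, "F"): f"lam_{ind}" for ind in inds}
    fixed = {f"lam_{inds[0]}": 1.0, "alpha_F": 0.0}
    paths = (("x", "F", "b_x_F"),) if covariates else ()
    return ModelSpec(
        latents=(LatentDef("F", inds, inds[0]),),
        loadings=loadings,
        intercepts={ind: f"nu_{ind}" for ind in inds},
        latent_means={"F": "alpha_F"},
        covariate_paths=paths,
        latent_cov={("F", "F"): "psi_F"},
        residual_cov={(ind, ind): f"theta_{ind}" for ind in inds},
        fixed=fixed,
    )


def single_latent_data(
    n: int = 400, lams=(1.0, 2.0, 0.5), psi: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, np.sqrt(psi), size=n)
    lams = np.asarray(lams)
    Y = 0.5 + eta[:, None] * lams[None, :] + rng.standard_normal((n, len(lams)))
    return pd.DataFrame(Y, columns=[f"y{k}" for k in range(1, len(lams) + 1)])


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the emulated study composition (88 MDD + 50 HC)."""
    cohort, truth = generate_cohort(SimulationConfig(), seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def homogeneous_cohort():
    """Mid-sized cohort with no group heterogeneity, for common-model fits."""
    cfg = SimulationConfig(n_mdd=320, n_hc=180).homogeneous()
    cohort, truth = generate_cohort(cfg, seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def fast_options():
    return FitOptions(seed=0, n_restarts=1)
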