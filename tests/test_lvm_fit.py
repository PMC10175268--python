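"""Likelihood, starting values, single-group and multigroup estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from petbold import (
    FitError,
    FitOptions,
    SpecError,
    build_common_model,
    build_group_model,
    fit_ml,
    fit_multigroup,
    latent_correlation,
    negative_log_likelihood,
    starting_values,
)
from petbold.lvm_fit import GaussianLikelihood
from petbold.lvm_spec import GroupModelSpec
from conftest import single_latent_data, single_latent_spec


def closed_form_three_indicator(df: pd.DataFrame) -> dict:
    """Moment solution of the just-identified one-factor model (MLE uses the
    1/n covariance): psi = s12*s13/s23, lam2 = s23/s13, lam3 = s23/s12,
    theta_jj = s_jj - lam_j^2 psi, intercepts = column means."""
    S = np.cov(df.to_numpy().T, ddof=0)
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    psi = s12 * s13 / s23
    lam2, lam3 = s23 / s13, s23 / s12
    lams = np.array([1.0, lam2, lam3])
    out = {"psi_F": psi, "lam_y2": lam2, "lam_y3": lam3}
    for j, col in enumerate(df.columns):
        out[f"nu_{col}"] = df[col].mean()
        out[f"theta_{col}"] = S[j, j] - lams[j] ** 2 * psi
    return out


class TestLikelihood:
    def test_empty_table_gives_zero(self):
        spec = single_latent_spec(3)
        theta = dict.fromkeys(spec.free_parameters(), 0.5)
        assert negative_log_likelihood(spec, theta, single_latent_data(0)) == 0.0

    def test_saturated_fit_matches_closed_form_mvn_loglik(self):
        df = single_latent_data(300, seed=3)
        spec = single_latent_spec(3)
        fit = fit_ml(spec, df, options=FitOptions(seed=3))
        mean = df.mean().to_numpy()
        S = np.cov(df.to_numpy().T, ddof=0)
        ll = multivariate_normal(mean, S).logpdf(df.to_numpy()).sum()
        # just-identified model: its MLE saturates the 3x3 moment structure
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_inflating_residual_variances_degrades_likelihood_monotonically(self):
        df = single_latent_data(200, seed=4)
        spec = single_latent_spec(3)
        fit = fit_ml(spec, df, options=FitOptions(seed=4))
        vals = []
        for scale in (1.0, 2.0, 4.0, 8.0):
            theta = dict(fit.estimates)
            for k in theta:
                if k.startswith("theta_"):
                    theta[k] *= scale
            vals.append(negative_log_likelihood(spec, theta, df))
        assert vals[0] < vals[1] < vals[2] < vals[3]

    def test_analytic_gradient_matches_finite_differences(self):
        spec = build_common_model(include_caudate_putamen_cov=True)
        from petbold import SimulationConfig, generate_cohort

        cohort, _ = generate_cohort(SimulationConfig(n_mdd=40, n_hc=20), seed=2)
        engine = GaussianLikelihood([(spec, cohort.model_frame())])
        vec = engine.vector(starting_values(spec, cohort.model_frame()))
        _, grad = engine.nll_and_grad(vec)
        num = np.zeros_like(vec)
        for k in range(len(vec)):
            h = 1e-6 * max(abs(vec[k]), 0.05)
            up, dn = vec.copy(), vec.copy()
            up[k] += h
            dn[k] -= h
            num[k] = (engine.nll(up) - engine.nll(dn)) / (2 * h)
        assert np.allclose(grad, num, rtol=5e-5, atol=5e-5)


class TestStartingValues:
    def test_order_of_magnitude_against_truth(self, homogeneous_cohort):
        cohort, truth = homogeneous_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        theta0 = starting_values(spec, cohort.model_frame())
        for name in ("psi_PET_LV", "psi_fMRI_LV", "theta_fmri_amygdala"):
            assert 0.1 * truth[name] < theta0[name] < 10 * truth[name]
        assert all(np.isfinite(v) for v in theta0.values())

    def test_constant_column_rejected(self):
        df = single_latent_data(50, seed=1)
        df["y2"] = 3.14
        with pytest.raises(SpecError, match="y2"):
            starting_values(single_latent_spec(3), df)

    def test_constrained_parameters_share_one_start(self):
        gm = build_group_model(constrain_loadings=True)
        from petbold import SimulationConfig, generate_cohort

        cohort, _ = generate_cohort(SimulationConfig(), seed=3)
        frame = cohort.split_by_group()["MDD"]
        theta0 = starting_values(gm.specs["MDD"], frame)
        # a single shared loading start exists per latent
        assert "lam_PET_LV" in theta0 and "lam_fMRI_LV" in theta0


class TestFitML:
    def test_just_identified_model_equals_moment_solution(self):
        df = single_latent_data(500, seed=8)
        spec = single_latent_spec(3)
        fit = fit_ml(spec, df, options=FitOptions(seed=8))
        for name, val in closed_form_three_indicator(df).items():
            assert fit.estimates[name] == pytest.approx(val, abs=1e-6)

    def test_refit_from_optimum_is_a_fixed_point(self):
        df = single_latent_data(200, seed=9)
        spec = single_latent_spec(3)
        fit = fit_ml(spec, df, options=FitOptions(seed=9))
        refit = fit_ml(spec, df, options=FitOptions(seed=10), theta0=fit.estimates)
        for name in fit.estimates:
            assert refit.estimates[name] == pytest.approx(
                fit.estimates[name], abs=1e-5
            )

    def test_optimum_improves_on_start(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        frame = cohort.model_frame()
        theta0 = starting_values(spec, frame)
        fit = fit_ml(spec, frame, options=FitOptions(seed=0))
        assert -fit.loglik <= negative_log_likelihood(spec, theta0, frame)

    def test_vcov_diagonal_positive(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        fit = fit_ml(spec, cohort.model_frame(), options=FitOptions(seed=0))
        assert (np.diag(fit.vcov.to_numpy()) > 0).all()

    def test_reference_indicator_choice_leaves_correlation_invariant(
        self, homogeneous_cohort
    ):
        cohort, _ = homogeneous_cohort
        frame = cohort.model_frame()
        opts = FitOptions(seed=0, gtol=1e-8)
        fits = [
            fit_ml(
                build_common_model(
                    include_caudate_putamen_cov=True,
                    pet_reference=ref_pet,
                    fmri_reference=ref_fmri,
                ),
                frame,
                options=opts,
            )
            for ref_pet, ref_fmri in (("putamen", "amygdala"), ("caudate", "insula"))
        ]
        r = [latent_correlation(f).estimate for f in fits]
        assert r[0] == pytest.approx(r[1], abs=1e-6)


class TestMultigroup:
    def test_identical_shared_specs_reduce_to_pooled_fit(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        frame = cohort.model_frame()
        spec = build_common_model(include_caudate_putamen_cov=True)
        half = len(frame) // 2
        gm = GroupModelSpec(
            groups=("A", "B"),
            specs={"A": spec, "B": spec},
            shared=spec.free_parameters(),
        )
        joint = fit_multigroup(
            gm,
            {"A": frame.iloc[:half], "B": frame.iloc[half:]},
            options=FitOptions(seed=1),
        )
        pooled = fit_ml(spec, frame, options=FitOptions(seed=1))
        assert joint.loglik == pytest.approx(pooled.loglik, abs=1e-4)
        for name in pooled.estimates:
            assert joint.estimates[name] == pytest.approx(
                pooled.estimates[name], abs=1e-4
            )

    def test_group_specific_covariances_recovered(self):
        from petbold import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_mdd=3000, n_hc=3000, rho_mdd=0.5, rho_hc=0.0
        ).equal_loadings()
        cohort, truth = generate_cohort(cfg, seed=21)
        gm = build_group_model(include_caudate_putamen_cov=True, covariates=False)
        fit = fit_multigroup(gm, cohort.split_by_group(), options=FitOptions(seed=21))
        for g in ("MDD", "HC"):
            name = f"psi_PET_LV_fMRI_LV|{g}"
            assert abs(fit.estimates[name] - truth[name]) < 3 * fit.se(name)

    def test_joint_loglik_is_sum_of_group_blocks(self, default_cohort):
        cohort, _ = default_cohort
        gm = build_group_model(include_caudate_putamen_cov=True)
        fit = fit_multigroup(gm, cohort.split_by_group(), options=FitOptions(seed=2))
        assert fit.loglik == pytest.approx(
            sum(fit.group_logliks.values()), abs=1e-8
        )

    def test_constrained_loadings_never_beat_unconstrained(self, default_cohort):
        cohort, _ = default_cohort
        data = cohort.split_by_group()
        lls = {}
        for constrained in (True, False):
            gm = build_group_model(
                constrain_loadings=constrained, include_caudate_putamen_cov=True
            )
            lls[constrained] = fit_multigroup(
                gm, data, options=FitOptions(seed=3)
            ).loglik
        assert lls[True] <= lls[False] + 1e-6

    def test_empty_group_rejected(self, default_cohort):
        cohort, _ = default_cohort
        gm = build_group_model()
        data = cohort.split_by_group()
        data["HC"] = data["HC"].iloc[:0]
        with pytest.raises(SpecError):
            fit_multigroup(gm, data)
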