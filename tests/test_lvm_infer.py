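"""Latent correlation, Wald contrasts, score tests, model search, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from petbold import (
    CandidatePath,
    FitOptions,
    SimulationConfig,
    SpecError,
    build_common_model,
    build_group_model,
    fit_ml,
    fit_multigroup,
    generate_cohort,
    latent_correlation,
    model_search,
    score_test,
    sensitivity_loadings,
    wald_contrast,
)
from petbold.lvm_fit import FittedModel, ConvergenceRecord
from petbold.lvm_infer import _score_test_full, add_candidate, default_candidates


def _dummy_fit(psi11, psi22, psi12, vcov_scale=1e-4):
    """Hand-built FittedModel carrying only latent-covariance entries."""
    spec = build_common_model(covariates=False)
    names = ["psi_PET_LV", "psi_fMRI_LV", "psi_PET_LV_fMRI_LV"]
    est = dict.fromkeys(spec.free_parameters(), 0.1)
    est.update(dict(zip(names, (psi11, psi22, psi12))))
    all_names = list(est)
    vcov = pd.DataFrame(
        np.eye(len(all_names)) * vcov_scale, index=all_names, columns=all_names
    )
    return FittedModel(
        spec=spec,
        estimates=est,
        loglik=0.0,
        vcov=vcov,
        n=100,
        convergence=ConvergenceRecord(True, 1, 0.0, 0),
    )


class TestLatentCorrelation:
    def test_zero_covariance_gives_zero_correlation(self):
        res = latent_correlation(_dummy_fit(2.0, 3.0, 0.0))
        assert res.estimate == 0.0

    def test_unit_variances_pass_through_covariance(self):
        res = latent_correlation(_dummy_fit(1.0, 1.0, 0.2))
        assert res.estimate == pytest.approx(0.2)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(SpecError):
            latent_correlation(_dummy_fit(-1.0, 1.0, 0.1))

    def test_ci_contains_estimate_and_p_in_unit_interval(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        fit = fit_ml(spec, cohort.model_frame(), options=FitOptions(seed=1))
        res = latent_correlation(fit)
        assert res.ci[0] <= res.estimate <= res.ci[1]
        assert 0 <= res.p <= 1
        assert -1 <= res.estimate <= 1


class TestWaldContrast:
    def test_identical_groups_give_null_difference(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        frame = cohort.model_frame()
        half = frame.copy()
        gm = build_group_model(include_caudate_putamen_cov=True, covariates=False)
        # same data in both groups: the group-specific covariances coincide
        data = {"MDD": frame, "HC": frame.copy()}
        fit = fit_multigroup(gm, data, options=FitOptions(seed=2))
        res = wald_contrast(fit, *gm.psi12_names())
        assert abs(res.estimate) < 1e-4
        assert res.p > 0.99

    def test_absent_parameter_rejected(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model()
        fit = fit_ml(spec, cohort.model_frame(), options=FitOptions(seed=2))
        with pytest.raises(SpecError):
            wald_contrast(fit, "psi_PET_LV", "nope")


class TestScoreTest:
    def test_candidate_already_free_rejected(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        fit = fit_ml(spec, cohort.model_frame(), options=FitOptions(seed=3))
        with pytest.raises(SpecError):
            score_test(fit, CandidatePath("residual_cov", "pet_putamen", "pet_caudate"))

    def test_injected_residual_correlation_attains_smallest_p(self):
        cfg = SimulationConfig(n_mdd=600, n_hc=400).homogeneous(
            caudate_putamen_resid_corr=0.5
        )
        spec = build_common_model()
        target = "residual_cov:pet_putamen~pet_caudate"
        for seed in (31, 32, 33):
            cohort, _ = generate_cohort(cfg, seed=seed)
            fit = fit_ml(spec, cohort.model_frame(), options=FitOptions(seed=seed))
            ps = {c.label: score_test(fit, c).p for c in default_candidates(spec)}
            assert min(ps, key=ps.get) == target

    def test_wald_score_lr_agree_asymptotically(self):
        # the three classical tests of one parameter differ pairwise by <10%
        # at n = 5000
        cfg = SimulationConfig(n_mdd=3000, n_hc=2000).homogeneous(
            caudate_putamen_resid_corr=0.08
        )
        cohort, _ = generate_cohort(cfg, seed=17)
        frame = cohort.model_frame()
        spec = build_common_model()
        cand = CandidatePath("residual_cov", "pet_putamen", "pet_caudate")
        fit0 = fit_ml(spec, frame, options=FitOptions(seed=17))
        score_stat, _ = _score_test_full(fit0, cand)
        aug, prm = add_candidate(spec, cand)
        fit1 = fit_ml(
            aug, frame, options=FitOptions(seed=17),
            theta0={**fit0.estimates, prm: 0.0},
        )
        lr_stat = 2 * (fit1.loglik - fit0.loglik)
        wald_stat = (fit1.estimates[prm] / fit1.se(prm)) ** 2
        stats = np.array([wald_stat, score_stat, lr_stat])
        for a in stats:
            for b in stats:
                assert abs(a - b) / max(a, b) < 0.10


class TestModelSearch:
    def test_empty_candidate_set_returns_spec_unchanged(self, homogeneous_cohort):
        cohort, _ = homogeneous_cohort
        spec = build_common_model()
        final, trail = model_search(spec, cohort.model_frame(), candidates=[])
        assert final is spec
        assert trail.rounds == []

    def test_holm_adjustment_never_below_raw(self, default_cohort):
        cohort, _ = default_cohort
        spec = build_common_model()
        _, trail = model_search(
            spec,
            cohort.model_frame(),
            default_candidates(spec)[:8],
            options=FitOptions(seed=5),
        )
        for rnd in trail.rounds:
            assert all(a >= r - 1e-12 for a, r in zip(rnd.adjusted_p, rnd.raw_p))

    def test_trail_is_deterministic(self, default_cohort):
        cohort, _ = default_cohort
        spec = build_common_model()
        frames = []
        for _ in range(2):
            _, trail = model_search(
                spec, cohort.model_frame(), options=FitOptions(seed=6)
            )
            frames.append(trail.frame())
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_search_finds_injected_path_then_stops(self):
        cfg = SimulationConfig(n_mdd=600, n_hc=400)
        cohort, _ = generate_cohort(cfg, seed=41)
        spec = build_common_model()
        final, trail = model_search(
            spec, cohort.model_frame(), options=FitOptions(seed=41)
        )
        assert [c.label for c in trail.accepted] == [
            "residual_cov:pet_putamen~pet_caudate"
        ]
        assert ("pet_putamen", "pet_caudate") in final.residual_cov
        assert trail.rounds[-1].accepted is None

    def test_overlapping_candidate_rejected(self, default_cohort):
        cohort, _ = default_cohort
        spec = build_common_model(include_caudate_putamen_cov=True)
        with pytest.raises(SpecError):
            model_search(
                spec,
                cohort.model_frame(),
                [CandidatePath("residual_cov", "pet_putamen", "pet_caudate")],
            )


class TestSensitivity:
    def test_constrained_and_unconstrained_agree_under_constrained_truth(self):
        cfg = SimulationConfig(n_mdd=300, n_hc=200).equal_loadings()
        cohort, _ = generate_cohort(cfg, seed=51)
        res = sensitivity_loadings(
            cohort.split_by_group(),
            extra_residual_cov=[("pet_putamen", "pet_caudate")],
            options=FitOptions(seed=51),
        )
        assert res.unconstrained_converged
        assert np.sign(res.constrained.estimate) == np.sign(
            res.unconstrained.estimate
        )
        # equal-correlation truth: neither variant should reject strongly
        assert res.constrained.p > 0.05
        assert res.unconstrained.p > 0.05
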