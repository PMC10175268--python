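"""Model specification: construction, parameter bookkeeping, implied moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petbold import (
    CohortTable,
    SpecError,
    build_common_model,
    build_group_model,
    implied_moments,
)
from petbold.lvm_spec import load_spec, save_spec, spec_from_dict, spec_to_dict
from conftest import single_latent_spec

import pandas as pd


class TestCommonModel:
    def test_structure_and_free_parameter_count(self):
        spec = build_common_model()
        assert len(spec.indicators) == 10
        assert spec.latent_names == ("PET_LV", "fMRI_LV")
        # hand count: 8 loadings + 10 intercepts + 10 residual variances
        # + 2 latent variances + 1 latent covariance + 6 covariate paths
        assert len(spec.free_parameters()) == 37
        spec2 = build_common_model(include_caudate_putamen_cov=True)
        assert len(spec2.free_parameters()) == 38

    def test_without_flag_no_offdiagonal_residuals(self):
        spec = build_common_model()
        assert all(a == b for a, b in spec.residual_cov)

    def test_covariate_targets(self):
        spec = build_common_model()
        pet_only = {c for c, t, _ in spec.covariate_paths if t == "PET_LV"}
        fmri = {c for c, t, _ in spec.covariate_paths if t == "fMRI_LV"}
        assert pet_only == {"age", "sex", "genotype", "inj_mass"}
        assert fmri == {"age", "sex"}

    @pytest.mark.parametrize(
        "pet,fmri",
        [(("putamen", "putamen"), ("amygdala",)), ((), ("amygdala",))],
    )
    def test_bad_roi_lists_rejected(self, pet, fmri):
        with pytest.raises(SpecError):
            build_common_model(pet, fmri)


class TestGroupModel:
    def test_constrained_loading_count(self):
        gm = build_group_model(constrain_loadings=True)
        loading_params = {
            p
            for g in gm.groups
            for (ind, lat), p in gm.specs[g].loadings.items()
            if p not in gm.specs[g].fixed
        }
        assert loading_params == {"lam_PET_LV", "lam_fMRI_LV"}

    def test_unconstrained_loading_count(self):
        gm = build_group_model(constrain_loadings=False)
        loading_params = {
            p
            for (ind, lat), p in gm.specs["MDD"].loadings.items()
            if p not in gm.specs["MDD"].fixed
        }
        assert len(loading_params) == 8

    def test_group_specific_latent_covariance_names(self):
        gm = build_group_model()
        n1, n2 = gm.psi12_names()
        assert n1 != n2
        assert {n1, n2} == {
            "psi_PET_LV_fMRI_LV|MDD",
            "psi_PET_LV_fMRI_LV|HC",
        }

    def test_constraint_release_is_exactly_the_loadings(self):
        con = build_group_model(constrain_loadings=True)
        unc = build_group_model(constrain_loadings=False)
        diff = set(unc.specs["MDD"].free_parameters()) - set(
            con.specs["MDD"].free_parameters()
        )
        assert diff == {
            f"lam_{ind}"
            for ind in unc.specs["MDD"].indicators
            if ind not in ("pet_putamen", "fmri_amygdala")
        }
        # 8 free per-indicator loadings replace 2 shared ones
        assert len(unc.specs["MDD"].free_parameters()) - len(
            con.specs["MDD"].free_parameters()
        ) == 6

    def test_covariates_attach_to_indicators(self):
        gm = build_group_model()
        targets = {t for _c, t, _p in gm.specs["MDD"].covariate_paths}
        assert targets <= set(gm.specs["MDD"].indicators)


class TestImpliedMoments:
    def test_zero_structure_collapses_to_theta(self):
        spec = single_latent_spec(3)
        theta = {
            "lam_y2": 0.0,
            "lam_y3": 0.0,
            "psi_F": 0.0,
            "nu_y1": 0.0,
            "nu_y2": 0.0,
            "nu_y3": 0.0,
            "theta_y1": 1.0,
            "theta_y2": 2.0,
            "theta_y3": 3.0,
        }
        # psi = 0 is singular, so skip the PD check; the reference loading of
        # 1 then multiplies a zero-variance latent
        _, Sigma = implied_moments(spec, theta, check=False)
        assert np.allclose(Sigma, np.diag([1.0, 2.0, 3.0]))

    def test_hand_computed_three_indicator_covariance(self):
        spec = single_latent_spec(3)
        theta = {
            "lam_y2": 2.0,
            "lam_y3": 0.5,
            "psi_F": 1.0,
            **{f"nu_y{k}": 0.0 for k in (1, 2, 3)},
            **{f"theta_y{k}": 1.0 for k in (1, 2, 3)},
        }
        _, Sigma = implied_moments(spec, theta)
        expect = np.array(
            [[2.0, 2.0, 0.5], [2.0, 5.0, 1.0], [0.5, 1.0, 1.25]]
        )
        assert np.allclose(Sigma, expect)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sigma_symmetric_positive_definite_for_valid_theta(self, seed):
        rng = np.random.default_rng(seed)
        spec = build_common_model(include_caudate_putamen_cov=True)
        theta = {}
        for name in spec.free_parameters():
            if name.startswith(("psi_PET_LV", "psi_fMRI_LV")) and "_fMRI" not in name[4:]:
                theta[name] = float(rng.uniform(0.1, 2.0))
            elif name.startswith("theta_") and name.count("pet_") + name.count("fmri_") == 1:
                theta[name] = float(rng.uniform(0.1, 2.0))
            else:
                theta[name] = float(rng.normal(0, 0.5))
        # keep Psi and Theta PD: bound off-diagonals by the variances
        theta["psi_PET_LV_fMRI_LV"] = 0.5 * np.sqrt(
            theta["psi_PET_LV"] * theta["psi_fMRI_LV"]
        )
        theta["theta_pet_putamen_pet_caudate"] = 0.5 * np.sqrt(
            theta["theta_pet_putamen"] * theta["theta_pet_caudate"]
        )
        x = {c: float(rng.normal()) for c in spec.covariates}
        _, Sigma = implied_moments(spec, theta, x)
        assert np.allclose(Sigma, Sigma.T, atol=1e-14)
        assert np.linalg.eigvalsh(Sigma).min() > 0

    def test_missing_covariate_raises(self):
        spec = build_common_model()
        theta = {n: 0.5 for n in spec.free_parameters()}
        with pytest.raises(SpecError):
            implied_moments(spec, theta, {"age": 0.0})


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        spec = build_common_model(include_caudate_putamen_cov=True)
        path = tmp_path / "spec.yaml"
        save_spec(spec, path)
        back = load_spec(path)
        assert spec_to_dict(back) == spec_to_dict(spec)

    def test_packaged_fixture_matches_builder(self):
        import petbold

        pkg_dir = __import__("pathlib").Path(petbold.__file__).parent
        fixture = load_spec(pkg_dir / "configs" / "common_model.yaml")
        assert spec_to_dict(fixture) == spec_to_dict(build_common_model())


class TestCohortTable:
    def _df(self, cohort):
        return cohort.df.copy()

    def test_positivity_enforced(self, default_cohort):
        df = self._df(default_cohort[0])
        df.loc[0, "pet_caudate"] = 0.0
        with pytest.raises(SpecError, match="pet_caudate"):
            CohortTable(df)

    def test_unknown_group_rejected(self, default_cohort):
        df = self._df(default_cohort[0])
        df.loc[0, "group"] = "other"
        with pytest.raises(SpecError, match="group"):
            CohortTable(df)

    def test_complete_cases_counts_dropped(self, default_cohort):
        df = self._df(default_cohort[0])
        df.loc[[1, 5], "fmri_insula"] = np.nan
        table, dropped = CohortTable(df).complete_cases()
        assert dropped == 2
        assert len(table) == len(df) - 2

    def test_model_frame_logs_pet_and_centers(self, default_cohort):
        cohort = default_cohort[0]
        frame = cohort.model_frame()
        assert np.allclose(
            frame["pet_putamen"], np.log(cohort.df["pet_putamen"])
        )
        assert abs(frame["age"].mean()) < 1e-10
        assert set(frame["sex"].unique()) <= {0.0, 1.0}
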