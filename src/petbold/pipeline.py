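"""End-to-end analysis pipeline and calibration studies.

``run_full_analysis`` executes the full sequence on one cohort table:
completeness filter, log transform of the PET columns, demographic
comparison table, common-model fit, score-test model search, latent
correlation, group-specific (constrained-loadings) fit, the group-moderation
Wald test on the latent covariance, and the unconstrained-loadings
sensitivity re-run.  ``calibrate_*`` run replicated simulation studies
(type-I error of the moderation and score tests, family-wise error of the
search) used by the test-bench CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import DemographicsTable, demographics_table
from .lvm_fit import FitError, FitOptions, FittedModel, MultigroupFit, fit_ml, fit_multigroup
from .lvm_infer import (
    CandidatePath,
    InferenceResult,
    SearchTrail,
    default_candidates,
    latent_correlation,
    latent_correlation_difference,
    model_search,
    score_test,
    sensitivity_loadings,
    wald_contrast,
    SensitivityResult,
)
from .lvm_spec import (
    FMRI_ROIS,
    GROUPS,
    PET_ROIS,
    CohortTable,
    SpecError,
    build_common_model,
    build_group_model,
)
from .synthetic import SimulationConfig, generate_cohort

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "validate_input",
    "run_full_analysis",
    "calibrate_moderation",
    "calibrate_score_type1",
    "calibrate_search_fwer",
    "CalibrationResult",
]

logger = logging.getLogger("petbold")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_csv`` / ``simulation`` must be set; ``seed``
    governs every random element of the run (simulation and optimiser
    restarts alike).
    """

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    pet_rois: tuple[str, ...] = PET_ROIS
    fmri_rois: tuple[str, ...] = FMRI_ROIS
    alpha: float = 0.05
    fwer_method: str = "holm"
    candidate_kinds: tuple[str, ...] = ("residual_cov", "loading")
    constrain_loadings: bool = True
    carry_search_paths: bool = True
    run_sensitivity: bool = True
    covariates: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulation is None):
            raise SpecError("set exactly one of input_csv / simulation")
        if not 0 < self.alpha < 1:
            raise SpecError("alpha must be in (0, 1)")


def validate_input(path) -> CohortTable:
    """Read and schema-check a cohort CSV.

    Enforces required columns, two-level group labels and strictly positive
    BP_ND; unknown extra columns are logged and ignored.  Rows with missing
    modeled values survive validation (the pipeline drops and counts them).
    """
    df = pd.read_csv(path)
    probe = CohortTable(df)
    extra = [c for c in df.columns if c not in probe.df.columns]
    if extra:
        logger.warning("ignoring unrecognized columns: %s", extra)
    return probe


@dataclass
class AnalysisReport:
    """Every statistic of one full run, in execution order."""

    n_input: int
    n_dropped: int
    n_by_group: dict[str, int]
    demographics: DemographicsTable
    common_fit: FittedModel
    search_trail: SearchTrail
    accepted_paths: list[str]
    latent_corr: InferenceResult
    group_fit: MultigroupFit
    moderation: InferenceResult
    moderation_corr_scale: InferenceResult
    group_latent_corr: dict[str, InferenceResult]
    sensitivity: SensitivityResult | None

    def to_dict(self) -> dict:
        def res(r: InferenceResult | None):
            if r is None:
                return None
            return {
                "name": r.name,
                "estimate": r.estimate,
                "se": r.se,
                "ci": list(r.ci),
                "p": r.p,
                "family": r.family,
            }

        return {
            "n_input": self.n_input,
            "n_dropped": self.n_dropped,
            "n_by_group": self.n_by_group,
            "demographics": self.demographics.frame.drop(columns=["kind"]).to_dict(
                orient="records"
            ),
            "common_fit": {
                "loglik": self.common_fit.loglik,
                "estimates": self.common_fit.estimates,
                "converged": self.common_fit.convergence.converged,
            },
            "search": {
                "accepted_paths": self.accepted_paths,
                "trail": self.search_trail.frame().to_dict(orient="records"),
            },
            "latent_correlation": res(self.latent_corr),
            "group_fit": {
                "loglik": self.group_fit.loglik,
                "estimates": self.group_fit.estimates,
                "converged": self.group_fit.convergence.converged,
            },
            "moderation": res(self.moderation),
            "moderation_correlation_scale": res(self.moderation_corr_scale),
            "group_latent_correlation": {
                g: res(r) for g, r in self.group_latent_corr.items()
            },
            "sensitivity": None
            if self.sensitivity is None
            else {
                "constrained": res(self.sensitivity.constrained),
                "unconstrained": res(self.sensitivity.unconstrained),
                "unconstrained_converged": self.sensitivity.unconstrained_converged,
            },
        }

    def render_text(self) -> str:
        lines = [
            "PET-fMRI latent variable analysis report",
            "=" * 42,
            f"subjects: {self.n_input} read, {self.n_dropped} dropped "
            f"(incomplete), groups {self.n_by_group}",
            "",
            "Demographics",
            "-" * 12,
            self.demographics.render_text(),
            "",
            "Common model",
            "-" * 12,
            self.common_fit.report_text(),
            "",
            "Model search (score tests, FWER-adjusted)",
            "-" * 41,
            self.search_trail.frame().to_string(index=False)
            if self.search_trail.rounds
            else "(no candidates tested)",
            f"accepted paths: {self.accepted_paths or 'none'}",
            "",
            f"Latent correlation: {self.latent_corr}",
            "",
            "Group-specific model",
            "-" * 20,
            self.group_fit.report_text(),
            "",
            f"Moderation (covariance scale): {self.moderation}",
            f"Moderation (correlation scale): {self.moderation_corr_scale}",
        ]
        for g, r in self.group_latent_corr.items():
            lines.append(f"  {r}")
        if self.sensitivity is not None:
            s = self.sensitivity
            lines += [
                "",
                "Sensitivity (loading constraints)",
                "-" * 33,
                f"constrained:   {s.constrained}",
                f"unconstrained: {s.unconstrained if s.unconstrained else 'did not converge'}",
            ]
        lines.append("")
        return "\n".join(lines)


def run_full_analysis(cfg: RunConfig) -> AnalysisReport:
    """Execute the full analysis sequence on one cohort (loaded or simulated)."""
    if cfg.simulation is not None:
        cohort, _truth = generate_cohort(cfg.simulation, seed=cfg.seed)
    else:
        cohort = validate_input(cfg.input_csv)
    n_input = len(cohort)
    cohort, n_dropped = cohort.complete_cases()
    if n_dropped:
        logger.info("dropped %d incomplete rows", n_dropped)
    n_by_group = {g: int((cohort.df["group"] == g).sum()) for g in GROUPS}

    demo = demographics_table(cohort)
    frame = cohort.model_frame()
    options = FitOptions(seed=cfg.seed)

    common_spec = build_common_model(
        cfg.pet_rois, cfg.fmri_rois, covariates=cfg.covariates
    )
    candidates = default_candidates(common_spec, kinds=cfg.candidate_kinds)
    final_spec, trail = model_search(
        common_spec,
        frame,
        candidates,
        alpha=cfg.alpha,
        adjustment=cfg.fwer_method,
        options=options,
    )
    common_fit = fit_ml(final_spec, frame, options=options)
    corr = latent_correlation(common_fit)

    carried: list[tuple[str, str]] = []
    for cand in trail.accepted:
        if cand.kind == "residual_cov" and cfg.carry_search_paths:
            carried.append((cand.a, cand.b))
        elif cfg.carry_search_paths:
            logger.warning(
                "accepted path %s is not a residual covariance; not carried "
                "into the group model",
                cand.label,
            )
    gm = build_group_model(
        cfg.pet_rois,
        cfg.fmri_rois,
        constrain_loadings=cfg.constrain_loadings,
        extra_residual_cov=carried,
        covariates=cfg.covariates,
    )
    group_fit = fit_multigroup(gm, cohort.split_by_group(), options=options)
    n1, n2 = gm.psi12_names()
    moderation = wald_contrast(group_fit, n1, n2)
    moderation_r = latent_correlation_difference(group_fit)
    group_corr = {g: latent_correlation(group_fit, group=g) for g in gm.groups}

    sens = None
    if cfg.run_sensitivity:
        sens = sensitivity_loadings(
            cohort.split_by_group(),
            pet_rois=cfg.pet_rois,
            fmri_rois=cfg.fmri_rois,
            extra_residual_cov=carried,
            covariates=cfg.covariates,
            options=options,
        )

    report = AnalysisReport(
        n_input=n_input,
        n_dropped=n_dropped,
        n_by_group=n_by_group,
        demographics=demo,
        common_fit=common_fit,
        search_trail=trail,
        accepted_paths=[c.label for c in trail.accepted],
        latent_corr=corr,
        group_fit=group_fit,
        moderation=moderation,
        moderation_corr_scale=moderation_r,
        group_latent_corr=group_corr,
        sensitivity=sens,
    )
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(report.render_text())
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return report


# ------------------------------------------------------------------ calibration
@dataclass(frozen=True)
class CalibrationResult:
    rate: float
    n_reps: int
    n_failed: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.rate * (1 - self.rate) / self.n_reps))


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def calibrate_moderation(
    config: SimulationConfig | None = None,
    *,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    covariates: bool = False,
    options: FitOptions | None = None,
) -> CalibrationResult:
    """Rejection rate of the group-moderation Wald test over replicated
    cohorts drawn from ``config``.

    With the default config variant (equal latent correlations and equal
    non-reference loadings) the null holds exactly and the rate estimates
    the type-I error; raising ``rho_mdd`` vs ``rho_hc`` turns this into a
    power study.  Covariate paths are omitted by default for speed (the
    generator's covariate effects are near zero).
    """
    if config is None:
        config = SimulationConfig().equal_loadings()
    gm = build_group_model(
        constrain_loadings=True,
        include_caudate_putamen_cov=abs(config.caudate_putamen_resid_corr) > 0,
        covariates=covariates,
    )
    n1, n2 = gm.psi12_names()
    rejections = 0
    failed = 0
    for s in _rep_seeds(seed, n_reps):
        cohort, _ = generate_cohort(config, seed=s)
        opts = replace(options or FitOptions(), seed=s)
        try:
            fit = fit_multigroup(gm, cohort.split_by_group(), options=opts)
        except FitError:
            failed += 1
            continue
        res = wald_contrast(fit, n1, n2)
        rejections += res.p < alpha
    used = n_reps - failed
    if failed:
        logger.warning("moderation calibration: %d/%d fits failed", failed, n_reps)
    return CalibrationResult(rejections / used if used else np.nan, used, failed)


def calibrate_score_type1(
    config: SimulationConfig | None = None,
    *,
    candidate: CandidatePath | None = None,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    covariates: bool = True,
    options: FitOptions | None = None,
) -> CalibrationResult:
    """Type-I error of the score test for one omitted-at-truth path.

    Cohorts are drawn from a config with no caudate-putamen residual
    correlation, the common model is fitted, and the score test for that
    (truly absent) path is evaluated at level ``alpha``.  The default bench
    size is four times the emulated cohort so the chi-square reference of
    the score statistic is accurate (see the methods note on small-sample
    behaviour at the study's own size).
    """
    if config is None:
        config = SimulationConfig(n_mdd=352, n_hc=200).homogeneous(
            caudate_putamen_resid_corr=0.0
        )
    if candidate is None:
        candidate = CandidatePath("residual_cov", "pet_putamen", "pet_caudate")
    spec = build_common_model(covariates=covariates)
    rejections = 0
    failed = 0
    for s in _rep_seeds(seed, n_reps):
        cohort, _ = generate_cohort(config, seed=s)
        opts = replace(options or FitOptions(), seed=s)
        try:
            fit = fit_ml(spec, cohort.model_frame(), options=opts)
        except FitError:
            failed += 1
            continue
        rejections += score_test(fit, candidate).p < alpha
    used = n_reps - failed
    if failed:
        logger.warning("score calibration: %d/%d fits failed", failed, n_reps)
    return CalibrationResult(rejections / used if used else np.nan, used, failed)


def calibrate_search_fwer(
    config: SimulationConfig | None = None,
    *,
    n_candidates: int = 12,
    n_reps: int = 200,
    alpha: float = 0.05,
    adjustment: str = "holm",
    seed: int = 0,
    covariates: bool = True,
    options: FitOptions | None = None,
) -> CalibrationResult:
    """Probability that the model search adds any path under the global null
    (no omitted paths in the generator).  As for the score bench, the
    default size is four times the emulated cohort."""
    if config is None:
        config = SimulationConfig(n_mdd=352, n_hc=200).homogeneous(
            caudate_putamen_resid_corr=0.0
        )
    spec = build_common_model(covariates=covariates)
    candidates = default_candidates(spec)[:n_candidates]
    added = 0
    failed = 0
    for s in _rep_seeds(seed, n_reps):
        cohort, _ = generate_cohort(config, seed=s)
        opts = replace(options or FitOptions(), seed=s)
        try:
            _, trail = model_search(
                spec,
                cohort.model_frame(),
                candidates,
                alpha=alpha,
                adjustment=adjustment,
                options=opts,
            )
        except FitError:
            failed += 1
            continue
        added += len(trail.accepted) > 0
    used = n_reps - failed
    if failed:
        logger.warning("FWER calibration: %d/%d fits failed", failed, n_reps)
    return CalibrationResult(added / used if used else np.nan, used, failed)
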