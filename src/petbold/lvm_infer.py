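"""Inference on fitted latent variable models.

Four pieces sit here: (i) normalisation of the latent covariance to a
Pearson correlation with a delta-method standard error, (ii) the Wald test
for a group difference in the latent covariance (the moderation contrast),
(iii) Rao score tests for candidate paths omitted from a fitted model, and
(iv) the iterative, family-wise-error-controlled model search that frees one
path per round while any adjusted score p-value clears the significance
level.

Score tests are computed at the constrained MLE without re-estimation: the
candidate parameter is appended to the free set at its null value, the full
gradient U and observed information I are formed there, and the statistic is
U' I^{-1} U with one degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lvm_fit import FitOptions, FitError, FittedModel, GaussianLikelihood, MultigroupFit, fit_ml, fit_multigroup
from .lvm_spec import ModelSpec, SpecError, _ordered_pair, build_group_model

__all__ = [
    "InferenceResult",
    "CandidatePath",
    "SearchRound",
    "SearchTrail",
    "SensitivityResult",
    "latent_correlation",
    "latent_correlation_difference",
    "wald_contrast",
    "score_test",
    "model_search",
    "default_candidates",
    "add_candidate",
    "sensitivity_loadings",
]

logger = logging.getLogger("petbold")

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class InferenceResult:
    """One statistic: estimate, SE, 95% CI, two-sided p-value."""

    name: str
    estimate: float
    se: float
    ci: tuple[float, float]
    p: float
    family: str  # "wald" | "score"
    df: int = 1

    def __str__(self) -> str:
        return (
            f"{self.name}: {self.estimate:.4g} (SE {self.se:.3g}, "
            f"95% CI {self.ci[0]:.4g}:{self.ci[1]:.4g}, p = {self.p:.3g}, "
            f"{self.family})"
        )


class CandidatePath(NamedTuple):
    """A path absent from a spec that a score test may support.

    kind: "residual_cov" (a, b indicators), "loading" (a indicator, b
    latent) or "covariate" (a covariate, b indicator).
    """

    kind: str
    a: str
    b: str

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.a}~{self.b}"


# ----------------------------------------------------------- latent correlation
def _psi_names(spec: ModelSpec) -> tuple[str, str, str]:
    lats = spec.latent_names
    if len(lats) != 2:
        raise SpecError("latent correlation requires exactly two latents")
    alias = spec._alias_map()
    names = (
        spec.latent_cov[(lats[0], lats[0])],
        spec.latent_cov[(lats[1], lats[1])],
        spec.latent_cov[(lats[0], lats[1])],
    )
    return tuple(alias.get(n, n) for n in names)


def latent_correlation(fit: FittedModel, group: str | None = None) -> InferenceResult:
    """Latent covariance normalised to a Pearson correlation.

    r = psi_12 / sqrt(psi_11 psi_22); the standard error propagates the
    joint uncertainty of the three latent (co)variance estimates through
    the delta method, and the Wald p tests r = 0.
    """
    spec = fit.spec_for(group) if isinstance(fit, MultigroupFit) and group else fit.spec
    n11, n22, n12 = _psi_names(spec)
    psi11, psi22, psi12 = (fit.estimates[n] for n in (n11, n22, n12))
    if psi11 <= 0 or psi22 <= 0:
        raise SpecError("non-positive latent variance estimate")
    denom = float(np.sqrt(psi11 * psi22))
    r = psi12 / denom
    grad = np.array([-r / (2 * psi11), -r / (2 * psi22), 1.0 / denom])
    V = fit.vcov.loc[[n11, n22, n12], [n11, n22, n12]].to_numpy()
    se = float(np.sqrt(grad @ V @ grad))
    z = r / se if se > 0 else np.inf * np.sign(r)
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else (1.0 if r == 0 else 0.0)
    name = f"r[{group}]" if group else "r"
    return InferenceResult(name, float(r), se, (r - _Z95 * se, r + _Z95 * se), p, "wald")


def _corr_and_grad(est, names):
    n11, n22, n12 = names
    psi11, psi22, psi12 = est[n11], est[n22], est[n12]
    denom = float(np.sqrt(psi11 * psi22))
    r = psi12 / denom
    return r, {n11: -r / (2 * psi11), n22: -r / (2 * psi22), n12: 1.0 / denom}


def latent_correlation_difference(fit: MultigroupFit) -> InferenceResult:
    """Group difference of the latent correlation (delta method on the joint
    vcov); a secondary, correlation-scale view of the moderation contrast."""
    gm = fit.group_model
    g1, g2 = gm.groups
    names1 = _psi_names(gm.specs[g1])
    names2 = _psi_names(gm.specs[g2])
    r1, grad1 = _corr_and_grad(fit.estimates, names1)
    r2, grad2 = _corr_and_grad(fit.estimates, names2)
    grad = dict(grad1)
    for k, v in grad2.items():
        grad[k] = grad.get(k, 0.0) - v
    keys = list(grad)
    gvec = np.array([grad[k] for k in keys])
    V = fit.vcov.loc[keys, keys].to_numpy()
    diff = r1 - r2
    se = float(np.sqrt(gvec @ V @ gvec))
    z = diff / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return InferenceResult(
        f"r[{g1}]-r[{g2}]", float(diff), se,
        (diff - _Z95 * se, diff + _Z95 * se), p, "wald",
    )


def wald_contrast(fit: FittedModel, name1: str, name2: str) -> InferenceResult:
    """Wald test of the difference between two free parameters of one fit."""
    for nme in (name1, name2):
        if nme not in fit.estimates:
            raise SpecError(f"parameter {nme!r} not free in this fit")
    diff = fit.estimates[name1] - fit.estimates[name2]
    v = (
        fit.vcov.loc[name1, name1]
        + fit.vcov.loc[name2, name2]
        - 2.0 * fit.vcov.loc[name1, name2]
    )
    se = float(np.sqrt(max(v, 0.0)))
    z = diff / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return InferenceResult(
        f"{name1} - {name2}", float(diff), se,
        (diff - _Z95 * se, diff + _Z95 * se), p, "wald",
    )


# ------------------------------------------------------------------- score tests
def add_candidate(spec: ModelSpec, cand: CandidatePath) -> tuple[ModelSpec, str]:
    """Return a copy of ``spec`` with the candidate path freed, plus its
    parameter name.  Raises if the path already exists."""
    if cand.kind == "residual_cov":
        pair = _ordered_pair(spec.indicators, cand.a, cand.b)
        if pair in spec.residual_cov:
            raise SpecError(f"residual covariance {pair} already in the model")
        prm = f"theta_{pair[0]}_{pair[1]}"
        rc = dict(spec.residual_cov)
        rc[pair] = prm
        return replace(spec, residual_cov=rc), prm
    if cand.kind == "loading":
        if cand.b not in spec.latent_names:
            raise SpecError(f"unknown latent {cand.b!r}")
        if (cand.a, cand.b) in spec.loadings:
            raise SpecError(f"loading ({cand.a}, {cand.b}) already in the model")
        prm = f"lam_{cand.a}_on_{cand.b}"
        ld = dict(spec.loadings)
        ld[(cand.a, cand.b)] = prm
        return replace(spec, loadings=ld), prm
    if cand.kind == "covariate":
        for cov, target, p in spec.covariate_paths:
            if cov == cand.a and target == cand.b:
                raise SpecError(f"covariate path {cand.a}->{cand.b} already present")
        prm = f"g_{cand.a}_{cand.b}"
        paths = spec.covariate_paths + ((cand.a, cand.b, prm),)
        return replace(spec, covariate_paths=paths), prm
    raise SpecError(f"unknown candidate kind {cand.kind!r}")


def _augmented_engine(fit: FittedModel, cand: CandidatePath):
    """Engine for the spec augmented with ``cand`` over the fitted data,
    plus the parameter vector holding the MLE with the candidate at 0."""
    if isinstance(fit, MultigroupFit):
        gm = fit.group_model
        blocks = []
        for g, block in zip(gm.groups, fit.engine.blocks):
            aug_spec, prm = add_candidate(gm.specs[g], cand)
            df = pd.DataFrame(
                np.hstack([block.Y, block.X]),
                columns=list(aug_spec.indicators) + list(aug_spec.covariates),
            )
            blocks.append((aug_spec, df))
        engine = GaussianLikelihood(blocks)
    else:
        aug_spec, prm = add_candidate(fit.spec, cand)
        block = fit.engine.blocks[0]
        df = pd.DataFrame(
            np.hstack([block.Y, block.X]),
            columns=list(aug_spec.indicators) + list(aug_spec.covariates),
        )
        engine = GaussianLikelihood([(aug_spec, df)])
    theta = dict(fit.estimates)
    theta[prm] = 0.0
    return engine, engine.vector(theta), prm


def _score_from_border(fit, engine, vec, prm):
    """Score statistic using the base fit's stored information for the free
    block and a finite-difference border for the candidate row/column."""
    m = fit.information.shape[0]
    c = engine.index[prm]
    order = [engine.index[nme] for nme in fit.free_names]
    _, g = engine.nll_and_grad(vec)
    h = 1e-5
    up, dn = vec.copy(), vec.copy()
    up[c] += h
    dn[c] -= h
    _, gu = engine.nll_and_grad(up)
    _, gd = engine.nll_and_grad(dn)
    col = (gu - gd) / (2.0 * h)
    H = np.zeros((m + 1, m + 1))
    H[:m, :m] = fit.information
    H[:m, m] = col[order]
    H[m, :m] = col[order]
    H[m, m] = col[c]
    U = -np.concatenate([g[order], [g[c]]])
    try:
        sol = np.linalg.solve(H, U)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(H, U, rcond=None)[0]
    stat = float(U @ sol)
    Vfull = np.linalg.pinv(H) if np.linalg.det(H) == 0 else np.linalg.inv(H)
    one_step = float(sol[m])  # Newton step for the candidate from the null
    se = float(np.sqrt(max(Vfull[m, m], 0.0)))
    return stat, one_step, se


def _score_test_full(fit: FittedModel, cand: CandidatePath) -> tuple[float, InferenceResult]:
    engine, vec, prm = _augmented_engine(fit, cand)
    stat, one_step, se = _score_from_border(fit, engine, vec, prm)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    res = InferenceResult(
        cand.label, one_step, se,
        (one_step - _Z95 * se, one_step + _Z95 * se), p, "score",
    )
    return stat, res


def score_test(fit: FittedModel, cand: CandidatePath) -> InferenceResult:
    """Rao score test of one omitted path at the constrained MLE.

    The reported estimate/SE are the one-step (Newton) approximation for the
    candidate parameter from the null point; the p-value is chi-square with
    1 df on the score statistic.  The fit is not re-estimated.
    """
    return _score_test_full(fit, cand)[1]


def default_candidates(spec: ModelSpec, kinds=("residual_cov", "loading")) -> list[CandidatePath]:
    """All extra residual covariances among the indicators plus all
    cross-loadings not already in the spec."""
    out: list[CandidatePath] = []
    inds = spec.indicators
    if "residual_cov" in kinds:
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                if (inds[i], inds[j]) not in spec.residual_cov:
                    out.append(CandidatePath("residual_cov", inds[i], inds[j]))
    if "loading" in kinds:
        for lat in spec.latents:
            for ind in inds:
                if (ind, lat.name) not in spec.loadings:
                    out.append(CandidatePath("loading", ind, lat.name))
    return out


# ------------------------------------------------------------------ model search
@dataclass
class SearchRound:
    candidates: list[CandidatePath]
    statistics: list[float]
    raw_p: list[float]
    adjusted_p: list[float]
    accepted: CandidatePath | None


@dataclass
class SearchTrail:
    rounds: list[SearchRound]

    @property
    def accepted(self) -> list[CandidatePath]:
        return [r.accepted for r in self.rounds if r.accepted is not None]

    def frame(self) -> pd.DataFrame:
        rows = []
        for k, rnd in enumerate(self.rounds, start=1):
            for cand, stat, rp, ap in zip(
                rnd.candidates, rnd.statistics, rnd.raw_p, rnd.adjusted_p
            ):
                rows.append(
                    {
                        "round": k,
                        "path": cand.label,
                        "score_stat": stat,
                        "p_raw": rp,
                        "p_adjusted": ap,
                        "accepted": rnd.accepted == cand,
                    }
                )
        return pd.DataFrame(rows)


def model_search(
    spec: ModelSpec,
    data: pd.DataFrame,
    candidates: Sequence[CandidatePath] | None = None,
    *,
    alpha: float = 0.05,
    adjustment: str = "holm",
    options: FitOptions | None = None,
) -> tuple[ModelSpec, SearchTrail]:
    """Iterative score-test model search with family-wise error control.

    Each round fits the current spec, score-tests every remaining candidate,
    adjusts the p-values over that round's family (Holm by default,
    Bonferroni optionally), and frees the single path with the smallest
    adjusted p if it clears ``alpha``; the search stops when no adjusted p
    does.  Returns the augmented spec and the full trail.
    """
    if adjustment not in ("holm", "bonferroni"):
        raise SpecError(f"unknown adjustment {adjustment!r}")
    options = options or FitOptions()
    remaining = list(candidates) if candidates is not None else default_candidates(spec)
    free = set(spec.free_parameters())
    for cand in remaining:
        try:
            _, prm = add_candidate(spec, cand)
        except SpecError as e:
            raise SpecError(f"candidate {cand.label} overlaps the model: {e}") from e
    trail = SearchTrail(rounds=[])
    if not remaining:
        return spec, trail
    current = spec
    warm: Mapping[str, float] | None = None
    for _round in range(len(remaining) + 1):
        try:
            fit = fit_ml(current, data, options=options, theta0=warm)
        except FitError as e:
            e.trail = trail  # abort, carrying the rounds completed so far
            raise
        stats_, raws = [], []
        for cand in remaining:
            stat, res = _score_test_full(fit, cand)
            stats_.append(stat)
            raws.append(res.p)
        adj = multipletests(raws, alpha=alpha, method=adjustment)[1]
        order = np.lexsort((np.arange(len(remaining)), raws, adj))
        best = int(order[0])
        accepted = None
        if adj[best] < alpha:
            accepted = remaining[best]
        trail.rounds.append(
            SearchRound(
                candidates=list(remaining),
                statistics=stats_,
                raw_p=list(raws),
                adjusted_p=[float(a) for a in adj],
                accepted=accepted,
            )
        )
        if accepted is None:
            break
        current, prm = add_candidate(current, accepted)
        warm = dict(fit.estimates)
        warm[prm] = 0.0
        remaining = [c for c in remaining if c != accepted]
        if not remaining:
            break
    return current, trail


# --------------------------------------------------------------------- sensitivity
@dataclass
class SensitivityResult:
    """Moderation Wald test under constrained and unconstrained loadings.

    When the unconstrained variant fails to converge, ``unconstrained`` is
    None and ``unconstrained_converged`` is False — the constrained answer
    is never silently substituted."""

    constrained: InferenceResult
    unconstrained: InferenceResult | None
    unconstrained_converged: bool


def _moderation_from_fit(fit: MultigroupFit) -> InferenceResult:
    n1, n2 = fit.group_model.psi12_names()
    return wald_contrast(fit, n1, n2)


def sensitivity_loadings(
    data_by_group: Mapping[str, pd.DataFrame],
    *,
    pet_rois=None,
    fmri_rois=None,
    extra_residual_cov: Sequence[tuple[str, str]] = (),
    covariates: bool = True,
    options: FitOptions | None = None,
) -> SensitivityResult:
    """Run the group-moderation Wald test with and without the equal-loading
    constraint and report both."""
    from .lvm_spec import PET_ROIS, FMRI_ROIS

    pet_rois = pet_rois or PET_ROIS
    fmri_rois = fmri_rois or FMRI_ROIS
    results = {}
    failed = False
    for constrained in (True, False):
        gm = build_group_model(
            pet_rois,
            fmri_rois,
            constrain_loadings=constrained,
            extra_residual_cov=extra_residual_cov,
            covariates=covariates,
        )
        try:
            fit = fit_multigroup(gm, data_by_group, options=options)
            results[constrained] = _moderation_from_fit(fit)
        except FitError as e:
            if constrained:
                raise
            logger.warning("unconstrained-loadings fit did not converge: %s", e)
            results[constrained] = None
            failed = True
    return SensitivityResult(
        constrained=results[True],
        unconstrained=results[False],
        unconstrained_converged=not failed,
    )
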