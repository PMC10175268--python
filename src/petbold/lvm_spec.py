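"""Declarative linear Gaussian latent variable models and their implied moments.

The models handled here are two-block confirmatory factor structures with
covariate paths, of the kind used to relate regional PET receptor-binding
outcomes to regional fMRI task reactivity.  For an observed indicator vector
``y`` (length p), covariates ``x`` (length c) and latent factors ``eta``
(length K) the model is

    eta = alpha + B x + zeta,      zeta ~ N(0, Psi)
    y   = nu + Lambda eta + Gamma x + eps,   eps ~ N(0, Theta)

so that the model-implied moments are

    mu(x)  = nu + Lambda (alpha + B x) + Gamma x
    Sigma  = Lambda Psi Lambda' + Theta .

``Lambda`` holds the factor loadings (one reference loading per factor fixed
to 1 for identification), ``Psi`` the latent covariance matrix whose
off-diagonal entry, once normalised by the latent variances, is the latent
Pearson correlation of interest, and ``Theta`` the residual covariance
(diagonal plus any explicitly freed extra covariances, e.g. a shared
caudate--putamen residual correlation).

A :class:`ModelSpec` is purely declarative: parameters are named strings,
equality constraints are expressed either by reusing a name or through
``constraints`` sets, and fixed values (reference loadings, zero latent
means) live in ``fixed``.  Estimation is in :mod:`petbold.lvm_fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PET_ROIS",
    "FMRI_ROIS",
    "GROUPS",
    "COVARIATES",
    "SpecError",
    "InvalidParameters",
    "LatentDef",
    "ModelSpec",
    "GroupModelSpec",
    "CohortTable",
    "build_common_model",
    "build_group_model",
    "implied_moments",
    "save_spec",
    "load_spec",
]

#: Regions with serotonin-4 receptor binding potential (BP_ND) outcomes.
PET_ROIS = ("putamen", "caudate", "amygdala", "insula", "vmpfc", "dlpfc")
#: Regions with BOLD "faces vs shapes" contrast estimates.
FMRI_ROIS = ("amygdala", "insula", "vmpfc", "dlpfc")
GROUPS = ("MDD", "HC")
#: Subject-level covariates: age (years), sex (female = 1), 5-HTTLPR class
#: (S' carrier = 1), weight-adjusted injected tracer mass (ug/kg).
COVARIATES = ("age", "sex", "genotype", "inj_mass")

PET_LATENT = "PET_LV"
FMRI_LATENT = "fMRI_LV"


def pet_col(roi: str) -> str:
    return f"pet_{roi}"


def fmri_col(roi: str) -> str:
    return f"fmri_{roi}"


class SpecError(ValueError):
    """Malformed model specification or incompatible data."""


class InvalidParameters(ValueError):
    """Parameter point outside the valid region (non-PD Psi or Theta)."""


@dataclass(frozen=True)
class LatentDef:
    """One latent factor: its name, ordered indicators, and the reference
    indicator whose loading is fixed to 1."""

    name: str
    indicators: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if len(self.indicators) == 0:
            raise SpecError(f"latent {self.name!r} has no indicators")
        if len(set(self.indicators)) != len(self.indicators):
            raise SpecError(f"latent {self.name!r} has duplicate indicators")
        if self.reference not in self.indicators:
            raise SpecError(
                f"reference {self.reference!r} is not an indicator of {self.name!r}"
            )


@dataclass
class ModelSpec:
    """Declarative description of a linear Gaussian latent variable model.

    Parameters are named strings.  A name reused in several slots (or listed
    together in ``constraints``) denotes a single underlying free value;
    names in ``fixed`` are pinned to a constant.
    """

    latents: tuple[LatentDef, ...]
    loadings: dict[tuple[str, str], str]  # (indicator, latent) -> param
    intercepts: dict[str, str]  # indicator -> param
    latent_means: dict[str, str]  # latent -> param
    covariate_paths: tuple[tuple[str, str, str], ...]  # (covariate, target, param)
    latent_cov: dict[tuple[str, str], str]  # (latent_i, latent_j), i<=j order
    residual_cov: dict[tuple[str, str], str]  # (ind_i, ind_j), i<=j order
    constraints: tuple[tuple[str, ...], ...] = ()
    fixed: dict[str, float] = field(default_factory=dict)

    # ------------------------------------------------------------------ basics
    def __post_init__(self):
        self.validate()

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.latents)

    @property
    def indicators(self) -> tuple[str, ...]:
        out: list[str] = []
        for l in self.latents:
            out.extend(l.indicators)
        return tuple(out)

    @property
    def covariates(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cov, _target, _p in self.covariate_paths:
            if cov not in seen:
                seen.append(cov)
        return tuple(seen)

    def validate(self) -> None:
        inds = self.indicators
        if len(set(inds)) != len(inds):
            raise SpecError("an indicator belongs to more than one latent")
        lat_names = self.latent_names
        if len(set(lat_names)) != len(lat_names):
            raise SpecError("duplicate latent names")
        ind_set, lat_set = set(inds), set(lat_names)
        by_latent = {l.name: set(l.indicators) for l in self.latents}

        for l in self.latents:
            key = (l.reference, l.name)
            p = self.loadings.get(key)
            if p is None or self.fixed.get(p) != 1.0:
                raise SpecError(
                    f"reference loading of {l.name!r} must be present and fixed to 1"
                )
        for (ind, lat) in self.loadings:
            if ind not in ind_set or lat not in lat_set:
                raise SpecError(f"loading on unknown indicator/latent ({ind}, {lat})")
        for ind in inds:
            if ind not in self.intercepts:
                raise SpecError(f"missing intercept for {ind!r}")
        for lat in lat_names:
            if lat not in self.latent_means:
                raise SpecError(f"missing latent mean for {lat!r}")
        for cov, target, _p in self.covariate_paths:
            if target not in ind_set and target not in lat_set:
                raise SpecError(f"covariate path targets unknown node {target!r}")
        # A covariate must not hit both a latent and one of its own indicators.
        lat_targets = {(c, t) for c, t, _ in self.covariate_paths if t in lat_set}
        for cov, target, _p in self.covariate_paths:
            if target in ind_set:
                for lat, members in by_latent.items():
                    if target in members and (cov, lat) in lat_targets:
                        raise SpecError(
                            f"covariate {cov!r} targets latent {lat!r} and its "
                            f"indicator {target!r} in the same spec"
                        )
        idx = {ind: k for k, ind in enumerate(inds)}
        for (a, b) in self.residual_cov:
            if a not in ind_set or b not in ind_set:
                raise SpecError(f"residual covariance on unknown indicators ({a},{b})")
            if idx[a] > idx[b]:
                raise SpecError("residual_cov keys must be in indicator order")
        for ind in inds:
            if (ind, ind) not in self.residual_cov:
                raise SpecError(f"missing residual variance for {ind!r}")
        lidx = {l: k for k, l in enumerate(lat_names)}
        for (a, b) in self.latent_cov:
            if a not in lat_set or b not in lat_set or lidx[a] > lidx[b]:
                raise SpecError(f"bad latent covariance key ({a},{b})")
        for lat in lat_names:
            if (lat, lat) not in self.latent_cov:
                raise SpecError(f"missing latent variance for {lat!r}")
        # No parameter name may serve in two different roles.
        roles: dict[str, str] = {}
        for role, names in (
            ("loading", self.loadings.values()),
            ("intercept", self.intercepts.values()),
            ("latent_mean", self.latent_means.values()),
            ("covariate", [p for _, _, p in self.covariate_paths]),
            ("latent_cov", self.latent_cov.values()),
            ("residual_cov", self.residual_cov.values()),
        ):
            for name in names:
                if roles.setdefault(name, role) != role:
                    raise SpecError(
                        f"parameter {name!r} reused across roles "
                        f"({roles[name]} and {role})"
                    )

    # -------------------------------------------------------------- parameters
    def _alias_map(self) -> dict[str, str]:
        """Map each parameter name to its canonical (first-listed) alias."""
        out: dict[str, str] = {}
        for group in self.constraints:
            canon = group[0]
            for name in group:
                out[name] = canon
        return out

    def declared_parameters(self) -> tuple[str, ...]:
        """All parameter names in canonical slot order (before aliasing)."""
        names: list[str] = []
        seen: set[str] = set()

        def add(name: str) -> None:
            if name not in seen:
                seen.add(name)
                names.append(name)

        inds = self.indicators
        for l in self.latents:
            for ind in l.indicators:
                add(self.loadings[(ind, l.name)])
        for (ind, lat), p in self.loadings.items():
            add(p)  # cross-loadings, in insertion order
        for ind in inds:
            add(self.intercepts[ind])
        for lat in self.latent_names:
            add(self.latent_means[lat])
        for _cov, _target, p in self.covariate_paths:
            add(p)
        for key in self.latent_cov:
            add(self.latent_cov[key])
        for ind in inds:
            add(self.residual_cov[(ind, ind)])
        for key, p in self.residual_cov.items():
            add(p)
        return tuple(names)

    def free_parameters(self) -> tuple[str, ...]:
        """Ordered canonical names of the free parameters."""
        alias = self._alias_map()
        out: list[str] = []
        seen: set[str] = set()
        for name in self.declared_parameters():
            canon = alias.get(name, name)
            if canon in self.fixed or name in self.fixed:
                continue
            if canon not in seen:
                seen.add(canon)
                out.append(canon)
        return tuple(out)

    def resolve(self, name: str, theta: Mapping[str, float]) -> float:
        """Value of parameter ``name`` under assignment ``theta``."""
        if name in self.fixed:
            return float(self.fixed[name])
        canon = self._alias_map().get(name, name)
        if canon in self.fixed:
            return float(self.fixed[canon])
        try:
            return float(theta[canon])
        except KeyError:
            raise SpecError(f"missing value for parameter {name!r}") from None

    # ---------------------------------------------------------------- matrices
    def build_matrices(self, theta: Mapping[str, float]):
        """Assemble (nu, Lambda, Gamma, B, alpha, Psi, Theta) at ``theta``."""
        inds, lats, covs = self.indicators, self.latent_names, self.covariates
        p, K, c = len(inds), len(lats), len(covs)
        iidx = {v: k for k, v in enumerate(inds)}
        lidx = {v: k for k, v in enumerate(lats)}
        cidx = {v: k for k, v in enumerate(covs)}

        nu = np.array([self.resolve(self.intercepts[i], theta) for i in inds])
        alpha = np.array([self.resolve(self.latent_means[l], theta) for l in lats])
        Lam = np.zeros((p, K))
        for (ind, lat), prm in self.loadings.items():
            Lam[iidx[ind], lidx[lat]] = self.resolve(prm, theta)
        Gam = np.zeros((p, c))
        B = np.zeros((K, c))
        for cov, target, prm in self.covariate_paths:
            val = self.resolve(prm, theta)
            if target in lidx:
                B[lidx[target], cidx[cov]] = val
            else:
                Gam[iidx[target], cidx[cov]] = val
        Psi = np.zeros((K, K))
        for (a, b), prm in self.latent_cov.items():
            v = self.resolve(prm, theta)
            Psi[lidx[a], lidx[b]] = v
            Psi[lidx[b], lidx[a]] = v
        Theta = np.zeros((p, p))
        for (a, b), prm in self.residual_cov.items():
            v = self.resolve(prm, theta)
            Theta[iidx[a], iidx[b]] = v
            Theta[iidx[b], iidx[a]] = v
        return nu, Lam, Gam, B, alpha, Psi, Theta


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a)
        return True
    except np.linalg.LinAlgError:
        return False


def implied_moments(
    spec: ModelSpec,
    theta: Mapping[str, float],
    x: Mapping[str, float] | Sequence[float] | None = None,
    *,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector mu(x) and covariance Sigma.

    ``x`` supplies one value per covariate named in the spec (mapping or
    sequence in spec covariate order; may be omitted for covariate-free
    specs).  With ``check`` on, a non-positive-definite Psi or Theta raises
    :class:`InvalidParameters`.
    """
    nu, Lam, Gam, B, alpha, Psi, Theta = spec.build_matrices(theta)
    covs = spec.covariates
    if covs:
        if x is None:
            raise SpecError("spec has covariates but no covariate vector given")
        if isinstance(x, Mapping):
            try:
                xv = np.array([float(x[c]) for c in covs])
            except KeyError as e:
                raise SpecError(f"missing covariate {e.args[0]!r}") from None
        else:
            xv = np.asarray(x, dtype=float)
            if xv.shape != (len(covs),):
                raise SpecError("covariate vector has wrong length")
    else:
        xv = np.zeros(0)
    if check and (not _is_pd(Psi) or not _is_pd(Theta)):
        raise InvalidParameters("Psi or Theta is not positive definite")
    mu = nu + Lam @ (alpha + B @ xv) + Gam @ xv
    Sigma = Lam @ Psi @ Lam.T + Theta
    Sigma = (Sigma + Sigma.T) / 2.0
    return mu, Sigma


# ---------------------------------------------------------------------- builders
def _roi_checks(pet_rois: Sequence[str], fmri_rois: Sequence[str]) -> None:
    if len(pet_rois) == 0 or len(fmri_rois) == 0:
        raise SpecError("each latent needs at least one indicator")
    if len(set(pet_rois)) != len(pet_rois) or len(set(fmri_rois)) != len(fmri_rois):
        raise SpecError("duplicate ROI names")


def build_common_model(
    pet_rois: Sequence[str] = PET_ROIS,
    fmri_rois: Sequence[str] = FMRI_ROIS,
    *,
    include_caudate_putamen_cov: bool = False,
    covariates: bool = True,
    pet_reference: str | None = None,
    fmri_reference: str | None = None,
) -> ModelSpec:
    """Common (group-agnostic) two-latent model.

    PET_LV spans the log BP_ND indicators, fMRI_LV the reactivity contrasts.
    Age and sex feed both latents; 5-HTTLPR and injected tracer mass feed
    PET_LV only.  The latent covariance psi is free; latent means are fixed
    to 0 with free indicator intercepts.  The reference indicator (loading
    fixed at 1) is the first ROI of each block unless overridden.
    """
    _roi_checks(pet_rois, fmri_rois)
    pet_inds = tuple(pet_col(r) for r in pet_rois)
    fmri_inds = tuple(fmri_col(r) for r in fmri_rois)
    pet_ref = pet_col(pet_reference) if pet_reference else pet_inds[0]
    fmri_ref = fmri_col(fmri_reference) if fmri_reference else fmri_inds[0]
    latents = (
        LatentDef(PET_LATENT, pet_inds, pet_ref),
        LatentDef(FMRI_LATENT, fmri_inds, fmri_ref),
    )
    inds = pet_inds + fmri_inds
    loadings = {}
    fixed: dict[str, float] = {}
    for l in latents:
        for ind in l.indicators:
            prm = f"lam_{ind}"
            loadings[(ind, l.name)] = prm
            if ind == l.reference:
                fixed[prm] = 1.0
    intercepts = {ind: f"nu_{ind}" for ind in inds}
    latent_means = {l.name: f"alpha_{l.name}" for l in latents}
    for l in latents:
        fixed[f"alpha_{l.name}"] = 0.0
    paths: list[tuple[str, str, str]] = []
    if covariates:
        for cov in ("age", "sex"):
            for lat in (PET_LATENT, FMRI_LATENT):
                paths.append((cov, lat, f"b_{cov}_{lat}"))
        for cov in ("genotype", "inj_mass"):
            paths.append((cov, PET_LATENT, f"b_{cov}_{PET_LATENT}"))
    latent_cov = {
        (PET_LATENT, PET_LATENT): f"psi_{PET_LATENT}",
        (FMRI_LATENT, FMRI_LATENT): f"psi_{FMRI_LATENT}",
        (PET_LATENT, FMRI_LATENT): f"psi_{PET_LATENT}_{FMRI_LATENT}",
    }
    residual_cov = {(ind, ind): f"theta_{ind}" for ind in inds}
    if include_caudate_putamen_cov:
        pair = _ordered_pair(inds, pet_col("putamen"), pet_col("caudate"))
        residual_cov[pair] = f"theta_{pair[0]}_{pair[1]}"
    return ModelSpec(
        latents=latents,
        loadings=loadings,
        intercepts=intercepts,
        latent_means=latent_means,
        covariate_paths=tuple(paths),
        latent_cov=latent_cov,
        residual_cov=residual_cov,
        fixed=fixed,
    )


def _ordered_pair(inds: Sequence[str], a: str, b: str) -> tuple[str, str]:
    idx = {v: k for k, v in enumerate(inds)}
    if a not in idx or b not in idx:
        raise SpecError(f"unknown indicators for residual covariance ({a},{b})")
    return (a, b) if idx[a] < idx[b] else (b, a)


@dataclass
class GroupModelSpec:
    """A per-group pair of :class:`ModelSpec` with shared-parameter naming.

    Parameters shared across groups carry identical names in both specs;
    group-specific ones carry a ``|<group>`` suffix.  ``shared`` lists the
    shared free names.
    """

    groups: tuple[str, ...]
    specs: dict[str, ModelSpec]
    shared: tuple[str, ...]

    def psi12_names(self) -> tuple[str, str]:
        """Per-group names of the latent covariance parameter."""
        out = []
        for g in self.groups:
            spec = self.specs[g]
            lats = spec.latent_names
            out.append(spec.latent_cov[(lats[0], lats[1])])
        return tuple(out)


def build_group_model(
    pet_rois: Sequence[str] = PET_ROIS,
    fmri_rois: Sequence[str] = FMRI_ROIS,
    *,
    constrain_loadings: bool = True,
    include_caudate_putamen_cov: bool = False,
    extra_residual_cov: Sequence[tuple[str, str]] = (),
    covariates: bool = True,
    groups: Sequence[str] = GROUPS,
    reference_group: str | None = None,
) -> GroupModelSpec:
    """Group-specific two-latent model (MDD vs HC).

    Latent means and the full latent covariance matrix are group-specific
    (the reference group's latent means are fixed to 0); loadings,
    intercepts, residual (co)variances and covariate paths are shared.
    Covariate effects attach directly to the indicators rather than the
    latents.  With ``constrain_loadings`` every non-reference loading within
    a latent shares a single parameter (one per latent); without it each
    indicator has its own loading (sensitivity variant).
    """
    _roi_checks(pet_rois, fmri_rois)
    groups = tuple(groups)
    if len(groups) != 2:
        raise SpecError("exactly two groups are supported")
    ref_group = reference_group if reference_group is not None else groups[1]
    if ref_group not in groups:
        raise SpecError(f"reference group {ref_group!r} not in {groups}")
    pet_inds = tuple(pet_col(r) for r in pet_rois)
    fmri_inds = tuple(fmri_col(r) for r in fmri_rois)
    inds = pet_inds + fmri_inds
    latents = (
        LatentDef(PET_LATENT, pet_inds, pet_inds[0]),
        LatentDef(FMRI_LATENT, fmri_inds, fmri_inds[0]),
    )
    loadings = {}
    fixed_shared: dict[str, float] = {}
    for l in latents:
        for ind in l.indicators:
            if ind == l.reference:
                prm = f"lam_{ind}"
                fixed_shared[prm] = 1.0
            elif constrain_loadings:
                prm = f"lam_{l.name}"
            else:
                prm = f"lam_{ind}"
            loadings[(ind, l.name)] = prm
    intercepts = {ind: f"nu_{ind}" for ind in inds}
    paths: list[tuple[str, str, str]] = []
    if covariates:
        for cov in ("age", "sex"):
            for ind in inds:
                paths.append((cov, ind, f"g_{cov}_{ind}"))
        for cov in ("genotype", "inj_mass"):
            for ind in pet_inds:
                paths.append((cov, ind, f"g_{cov}_{ind}"))
    residual_cov = {(ind, ind): f"theta_{ind}" for ind in inds}
    extras = list(extra_residual_cov)
    if include_caudate_putamen_cov:
        extras.append((pet_col("putamen"), pet_col("caudate")))
    for a, b in extras:
        pair = _ordered_pair(inds, a, b)
        residual_cov[pair] = f"theta_{pair[0]}_{pair[1]}"

    specs: dict[str, ModelSpec] = {}
    for g in groups:
        fixed = dict(fixed_shared)
        latent_means = {}
        for l in latents:
            prm = f"alpha_{l.name}|{g}"
            latent_means[l.name] = prm
            if g == ref_group:
                fixed[prm] = 0.0
        latent_cov = {
            (PET_LATENT, PET_LATENT): f"psi_{PET_LATENT}|{g}",
            (FMRI_LATENT, FMRI_LATENT): f"psi_{FMRI_LATENT}|{g}",
            (PET_LATENT, FMRI_LATENT): f"psi_{PET_LATENT}_{FMRI_LATENT}|{g}",
        }
        specs[g] = ModelSpec(
            latents=latents,
            loadings=dict(loadings),
            intercepts=dict(intercepts),
            latent_means=latent_means,
            covariate_paths=tuple(paths),
            latent_cov=latent_cov,
            residual_cov=dict(residual_cov),
            fixed=fixed,
        )
    shared = tuple(
        n for n in specs[groups[0]].free_parameters()
        if n in set(specs[groups[1]].free_parameters())
    )
    return GroupModelSpec(groups=groups, specs=specs, shared=shared)


# ------------------------------------------------------------------ cohort table
class CohortTable:
    """Validated subject-level table: group label, covariates, and the ten
    regional outcomes (six PET BP_ND columns, strictly positive; four fMRI
    contrast columns)."""

    REQUIRED = ("id", "group") + COVARIATES

    def __init__(
        self,
        df: pd.DataFrame,
        pet_rois: Sequence[str] = PET_ROIS,
        fmri_rois: Sequence[str] = FMRI_ROIS,
        *,
        allow_missing: bool = True,
    ):
        self.pet_rois = tuple(pet_rois)
        self.fmri_rois = tuple(fmri_rois)
        cols = list(self.REQUIRED) + self.pet_columns + self.fmri_columns
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SpecError(f"missing required columns: {missing}")
        df = df.loc[:, cols].copy()
        bad_groups = set(df["group"].dropna().unique()) - set(GROUPS)
        if bad_groups:
            raise SpecError(f"unknown group labels: {sorted(bad_groups)}")
        for c in self.pet_columns:
            vals = df[c]
            if (vals.dropna() <= 0).any():
                raise SpecError(f"non-positive BP_ND in column {c!r}")
        if not allow_missing and df[self.modeled_columns].isna().any().any():
            raise SpecError("missing values present; run complete_cases() first")
        self.df = df.reset_index(drop=True)

    # Column groups ------------------------------------------------------
    @property
    def pet_columns(self) -> list[str]:
        return [pet_col(r) for r in self.pet_rois]

    @property
    def fmri_columns(self) -> list[str]:
        return [fmri_col(r) for r in self.fmri_rois]

    @property
    def modeled_columns(self) -> list[str]:
        return list(COVARIATES) + self.pet_columns + self.fmri_columns

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path, **kw) -> "CohortTable":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    # Filters and views --------------------------------------------------
    def complete_cases(self) -> tuple["CohortTable", int]:
        """Drop rows with any missing modeled variable; return (table, n_dropped)."""
        keep = ~self.df[self.modeled_columns].isna().any(axis=1)
        out = CohortTable(self.df.loc[keep], self.pet_rois, self.fmri_rois)
        return out, int((~keep).sum())

    def model_frame(self, *, center: bool = True) -> pd.DataFrame:
        """Analysis-ready frame: PET columns natural-log transformed (the
        indicator columns keep their names but hold log BP_ND), continuous
        covariates (age, injected mass) centered at the sample mean."""
        df = self.df.copy()
        for c in self.pet_columns:
            df[c] = np.log(df[c].to_numpy(float))
        if center:
            for c in ("age", "inj_mass"):
                df[c] = df[c] - df[c].mean()
        return df

    def split_by_group(self) -> dict[str, pd.DataFrame]:
        frame = self.model_frame()
        return {g: frame.loc[frame["group"] == g].reset_index(drop=True) for g in GROUPS}


# ---------------------------------------------------------------- serialization
def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "latents": [
            {"name": l.name, "indicators": list(l.indicators), "reference": l.reference}
            for l in spec.latents
        ],
        "loadings": [
            {"indicator": i, "latent": l, "param": p}
            for (i, l), p in spec.loadings.items()
        ],
        "intercepts": dict(spec.intercepts),
        "latent_means": dict(spec.latent_means),
        "covariate_paths": [list(t) for t in spec.covariate_paths],
        "latent_cov": [
            {"row": a, "col": b, "param": p} for (a, b), p in spec.latent_cov.items()
        ],
        "residual_cov": [
            {"row": a, "col": b, "param": p} for (a, b), p in spec.residual_cov.items()
        ],
        "constraints": [list(c) for c in spec.constraints],
        "fixed": dict(spec.fixed),
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    return ModelSpec(
        latents=tuple(
            LatentDef(x["name"], tuple(x["indicators"]), x["reference"])
            for x in d["latents"]
        ),
        loadings={(x["indicator"], x["latent"]): x["param"] for x in d["loadings"]},
        intercepts=dict(d["intercepts"]),
        latent_means=dict(d["latent_means"]),
        covariate_paths=tuple(tuple(t) for t in d["covariate_paths"]),
        latent_cov={(x["row"], x["col"]): x["param"] for x in d["latent_cov"]},
        residual_cov={(x["row"], x["col"]): x["param"] for x in d["residual_cov"]},
        constraints=tuple(tuple(c) for c in d.get("constraints", [])),
        fixed={k: float(v) for k, v in d.get("fixed", {}).items()},
    )


def save_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
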