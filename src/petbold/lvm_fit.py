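"""Maximum-likelihood estimation of the latent variable models.

Estimation maximises the multivariate-normal likelihood implied by a
:class:`~petbold.lvm_spec.ModelSpec`: each subject contributes
``log phi(y_i; mu(x_i), Sigma)`` with a subject-specific mean (through the
covariate paths) and a common covariance.  The optimiser is quasi-Newton
(BFGS) on the raw parameter scale with analytic gradients; parameter points
with a non-positive-definite Psi or Theta receive a large sentinel value so
the line search backs away.  Standard errors come from the inverse observed
information (numerical Hessian of the negative log-likelihood, built from
central differences of the analytic gradient).

Multigroup fits share parameters across groups purely through naming: the
per-group specs produced by :func:`petbold.lvm_spec.build_group_model` give
shared parameters identical names, so the joint likelihood is the sum of
group blocks over the union of free names and equality constraints hold
exactly by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .lvm_spec import GroupModelSpec, ModelSpec, SpecError

__all__ = [
    "FitOptions",
    "FitError",
    "ConvergenceRecord",
    "FittedModel",
    "MultigroupFit",
    "GaussianLikelihood",
    "negative_log_likelihood",
    "starting_values",
    "fit_ml",
    "fit_multigroup",
]

logger = logging.getLogger("petbold")

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12  # sentinel for invalid (non-PD) parameter points


@dataclass(frozen=True)
class FitOptions:
    """Optimisation settings.

    gtol is the gradient-norm target passed to BFGS; a fit is accepted when
    the final inf-norm of the gradient is below ``accept_gtol``.  Restarts
    jitter the starting point multiplicatively using ``seed``.
    """

    gtol: float = 1e-6
    accept_gtol: float = 1e-3
    max_iter: int = 2000
    n_restarts: int = 3
    seed: int = 0


@dataclass
class ConvergenceRecord:
    converged: bool
    n_iter: int
    grad_norm: float
    restarts_used: int
    message: str = ""


class FitError(RuntimeError):
    """Optimisation failed to converge; ``best`` carries the best point found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


# ----------------------------------------------------------------- compilation
class _Block:
    """One (spec, data) block compiled to index arrays for fast evaluation."""

    _MATS = ("nu", "Lam", "Gam", "B", "alpha", "Psi", "Theta")

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, free_index: Mapping[str, int]):
        self.spec = spec
        inds, lats, covs = spec.indicators, spec.latent_names, spec.covariates
        missing = [c for c in list(inds) + list(covs) if c not in data.columns]
        if missing:
            raise SpecError(f"data is missing modeled columns: {missing}")
        self.Y = data.loc[:, list(inds)].to_numpy(float)
        self.X = (
            data.loc[:, list(covs)].to_numpy(float)
            if covs
            else np.zeros((len(data), 0))
        )
        if np.isnan(self.Y).any() or np.isnan(self.X).any():
            raise SpecError("NaN in modeled columns; apply complete_cases() first")
        self.n, self.p = self.Y.shape
        self.K, self.c = len(lats), len(covs)
        iidx = {v: k for k, v in enumerate(inds)}
        lidx = {v: k for k, v in enumerate(lats)}
        cidx = {v: k for k, v in enumerate(covs)}
        alias = spec._alias_map()

        # entries: (matrix name, i, j, free index or -1, fixed value, sym factor)
        entries: list[tuple[str, int, int, int, float, float]] = []

        def src(prm: str) -> tuple[int, float]:
            if prm in spec.fixed:
                return -1, float(spec.fixed[prm])
            canon = alias.get(prm, prm)
            if canon in spec.fixed:
                return -1, float(spec.fixed[canon])
            return free_index[canon], 0.0

        for ind in inds:
            k, v = src(spec.intercepts[ind])
            entries.append(("nu", iidx[ind], 0, k, v, 1.0))
        for (ind, lat), prm in spec.loadings.items():
            k, v = src(prm)
            entries.append(("Lam", iidx[ind], lidx[lat], k, v, 1.0))
        for cov, target, prm in spec.covariate_paths:
            k, v = src(prm)
            if target in lidx:
                entries.append(("B", lidx[target], cidx[cov], k, v, 1.0))
            else:
                entries.append(("Gam", iidx[target], cidx[cov], k, v, 1.0))
        for lat in lats:
            k, v = src(spec.latent_means[lat])
            entries.append(("alpha", lidx[lat], 0, k, v, 1.0))
        for (a, b), prm in spec.latent_cov.items():
            k, v = src(prm)
            fac = 1.0 if a == b else 2.0
            entries.append(("Psi", lidx[a], lidx[b], k, v, fac))
        for (a, b), prm in spec.residual_cov.items():
            k, v = src(prm)
            fac = 1.0 if a == b else 2.0
            entries.append(("Theta", iidx[a], iidx[b], k, v, fac))
        self.entries = entries

    def matrices(self, theta: np.ndarray):
        p, K, c = self.p, self.K, self.c
        mats = {
            "nu": np.zeros((p, 1)),
            "Lam": np.zeros((p, K)),
            "Gam": np.zeros((p, c)),
            "B": np.zeros((K, c)),
            "alpha": np.zeros((K, 1)),
            "Psi": np.zeros((K, K)),
            "Theta": np.zeros((p, p)),
        }
        for name, i, j, k, v, _fac in self.entries:
            val = theta[k] if k >= 0 else v
            mats[name][i, j] = val
            if name in ("Psi", "Theta") and i != j:
                mats[name][j, i] = val
        return mats

    def nll_grad(self, theta: np.ndarray, grad_out: np.ndarray | None):
        """Negative log-likelihood of this block; accumulates the gradient
        into ``grad_out`` (global free vector layout) when given."""
        m = self.matrices(theta)
        nu = m["nu"][:, 0]
        alpha = m["alpha"][:, 0]
        Lam, Gam, B, Psi, Theta = m["Lam"], m["Gam"], m["B"], m["Psi"], m["Theta"]
        # validity: Psi and Theta must both be PD
        try:
            np.linalg.cholesky(Psi)
            np.linalg.cholesky(Theta)
            Sigma = Lam @ Psi @ Lam.T + Theta
            cf = cho_factor((Sigma + Sigma.T) / 2.0, lower=True)
        except np.linalg.LinAlgError:
            return None
        n = self.n
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        M = alpha[None, :] + self.X @ B.T  # (n, K) latent means per subject
        Mu = nu[None, :] + M @ Lam.T + self.X @ Gam.T
        R = self.Y - Mu
        Q = cho_solve(cf, R.T)  # Sigma^{-1} R'  (p, n)
        quad = float(np.sum(R.T * Q))
        nll = 0.5 * (n * self.p * _LOG2PI + n * logdet + quad)
        if grad_out is None:
            return nll

        Sinv = cho_solve(cf, np.eye(self.p))
        S = R.T @ R / n
        G = 0.5 * n * (Sinv - Sinv @ S @ Sinv)
        qs = Q.sum(axis=1)  # Sigma^{-1} sum_i r_i
        QX = Q @ self.X  # (p, c)
        d = {
            "nu": (-qs)[:, None],
            "Gam": -QX,
            "B": -(Lam.T @ QX),
            "alpha": (-(Lam.T @ qs))[:, None],
            "Lam": 2.0 * G @ Lam @ Psi - Q @ M,
            "Psi": Lam.T @ G @ Lam,
            "Theta": G,
        }
        for name, i, j, k, _v, fac in self.entries:
            if k >= 0:
                grad_out[k] += fac * d[name][i, j]
        return nll


class GaussianLikelihood:
    """Joint Gaussian likelihood over one or more (spec, data) blocks.

    Blocks share parameters through identical canonical names; the free
    vector is the ordered union of the blocks' free parameters.
    """

    def __init__(self, blocks: Sequence[tuple[ModelSpec, pd.DataFrame]]):
        names: list[str] = []
        seen: set[str] = set()
        for spec, _df in blocks:
            for nme in spec.free_parameters():
                if nme not in seen:
                    seen.add(nme)
                    names.append(nme)
        self.free_names: tuple[str, ...] = tuple(names)
        self.index = {nme: k for k, nme in enumerate(names)}
        self.blocks = [_Block(spec, df, self.index) for spec, df in blocks]
        self.n_total = sum(b.n for b in self.blocks)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def vector(self, theta: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([float(theta[nme]) for nme in self.free_names])
        except KeyError as e:
            raise SpecError(f"missing value for parameter {e.args[0]!r}") from None

    def as_dict(self, vec: np.ndarray) -> dict[str, float]:
        return {nme: float(v) for nme, v in zip(self.free_names, vec)}

    def nll(self, vec: np.ndarray) -> float:
        total = 0.0
        for b in self.blocks:
            v = b.nll_grad(vec, None)
            if v is None:
                return _BIG
            total += v
        return total

    def nll_and_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros(self.n_free)
        total = 0.0
        for b in self.blocks:
            v = b.nll_grad(vec, grad)
            if v is None:
                return _BIG, np.zeros(self.n_free)
            total += v
        return total, grad

    def block_nlls(self, vec: np.ndarray) -> list[float]:
        return [b.nll_grad(vec, None) for b in self.blocks]

    def observed_information(self, vec: np.ndarray) -> np.ndarray:
        """Numerical Hessian of the NLL via central differences of the
        analytic gradient."""
        m = self.n_free
        H = np.zeros((m, m))
        for k in range(m):
            h = 1e-4 * max(abs(vec[k]), 0.1)
            up, dn = vec.copy(), vec.copy()
            up[k] += h
            dn[k] -= h
            _, gu = self.nll_and_grad(up)
            _, gd = self.nll_and_grad(dn)
            H[:, k] = (gu - gd) / (2.0 * h)
        return (H + H.T) / 2.0


# -------------------------------------------------------------------- public ops
def negative_log_likelihood(
    spec: ModelSpec, theta: Mapping[str, float], data: pd.DataFrame
) -> float:
    """-sum_i log phi(y_i; mu(x_i), Sigma) at parameter assignment ``theta``.

    Returns the large sentinel value for non-positive-definite Psi/Theta.
    An empty table gives 0.
    """
    if len(data) == 0:
        return 0.0
    engine = GaussianLikelihood([(spec, data)])
    return engine.nll(engine.vector(theta))


def starting_values(spec: ModelSpec, data: pd.DataFrame) -> dict[str, float]:
    """Moment-based starting point.

    Intercepts start at column means, residual variances at half the column
    variances, loadings at covariances with the reference indicator scaled
    by the provisional latent variance (half the reference variance), and
    the latent covariance at half the covariance of the two reference
    indicators.  Covariate paths, latent means and extra residual
    covariances start at 0.  Aliased (equality-constrained) parameters get
    the mean of their members' proposals.
    """
    if len(data) == 0:
        raise SpecError("cannot compute starting values from an empty table")
    inds = spec.indicators
    cols = data.loc[:, list(inds)].to_numpy(float)
    if np.isnan(cols).any():
        raise SpecError("NaN in indicator columns")
    means = cols.mean(axis=0)
    covm = np.cov(cols, rowvar=False, ddof=0)
    covm = np.atleast_2d(covm)
    variances = np.diag(covm)
    degenerate = variances <= 1e-12 * np.maximum(1.0, means**2)
    if np.any(degenerate):
        bad = [inds[k] for k in np.where(degenerate)[0]]
        raise SpecError(f"zero-variance (degenerate) columns: {bad}")
    iidx = {v: k for k, v in enumerate(inds)}
    refs = {l.name: l.reference for l in spec.latents}
    psi0 = {lat: variances[iidx[ref]] / 2.0 for lat, ref in refs.items()}

    proposals: list[tuple[str, float]] = []
    for (ind, lat), prm in spec.loadings.items():
        if ind == refs[lat]:
            continue
        if ind in spec.latents[[l.name for l in spec.latents].index(lat)].indicators:
            val = covm[iidx[ind], iidx[refs[lat]]] / psi0[lat]
        else:
            val = 0.0
        proposals.append((prm, val))
    for ind in inds:
        proposals.append((spec.intercepts[ind], means[iidx[ind]]))
    for lat in spec.latent_names:
        proposals.append((spec.latent_means[lat], 0.0))
    for _cov, _target, prm in spec.covariate_paths:
        proposals.append((prm, 0.0))
    for (a, b), prm in spec.latent_cov.items():
        if a == b:
            proposals.append((prm, psi0[a]))
        else:
            proposals.append((prm, covm[iidx[refs[a]], iidx[refs[b]]] / 2.0))
    for (a, b), prm in spec.residual_cov.items():
        proposals.append((prm, variances[iidx[a]] / 2.0 if a == b else 0.0))

    alias = spec._alias_map()
    sums: dict[str, list[float]] = {}
    for prm, val in proposals:
        canon = alias.get(prm, prm)
        if canon in spec.fixed or prm in spec.fixed:
            continue
        sums.setdefault(canon, []).append(float(val))
    return {k: float(np.mean(v)) for k, v in sums.items()}


# ------------------------------------------------------------------- fit results
@dataclass
class FittedModel:
    """A converged single-group fit: estimates, log-likelihood, and the
    variance-covariance matrix of the estimates (inverse observed
    information)."""

    spec: ModelSpec
    estimates: dict[str, float]
    loglik: float
    vcov: pd.DataFrame
    n: int
    convergence: ConvergenceRecord
    information: np.ndarray = field(repr=False, default=None)
    engine: GaussianLikelihood = field(repr=False, default=None)

    @property
    def free_names(self) -> tuple[str, ...]:
        return self.engine.free_names

    def se(self, name: str) -> float:
        return float(np.sqrt(self.vcov.loc[name, name]))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for nme in self.free_names:
            est = self.estimates[nme]
            se = self.se(nme)
            rows.append(
                {
                    "parameter": nme,
                    "estimate": est,
                    "se": se,
                    "ci_lower": est - 1.96 * se,
                    "ci_upper": est + 1.96 * se,
                }
            )
        return pd.DataFrame(rows)

    def report_text(self) -> str:
        conv = self.convergence
        lines = [
            f"log-likelihood: {self.loglik:.6f}   n = {self.n}",
            f"convergence: converged={conv.converged} iter={conv.n_iter} "
            f"|grad|={conv.grad_norm:.3e} restarts={conv.restarts_used}",
            "",
            self.summary_frame().to_string(
                index=False, float_format=lambda v: f"{v:10.4f}"
            ),
        ]
        return "\n".join(lines)


@dataclass
class MultigroupFit(FittedModel):
    """Joint fit over per-group specs sharing constrained parameters.

    ``estimates``/``vcov`` cover the union of free parameters; the joint
    log-likelihood is the sum of the per-group contributions.
    """

    group_model: GroupModelSpec = None
    group_logliks: dict[str, float] = field(default_factory=dict)

    def spec_for(self, group: str) -> ModelSpec:
        return self.group_model.specs[group]


# ------------------------------------------------------------------- optimisation
def _optimize(
    engine: GaussianLikelihood, theta0: np.ndarray, options: FitOptions
) -> tuple[np.ndarray, float, ConvergenceRecord]:
    rng = np.random.default_rng(options.seed)
    # gradient magnitudes scale with the number of subjects; the acceptance
    # threshold follows (parameter-scale error stays ~1e-9 either way)
    accept = options.accept_gtol * max(1.0, engine.n_total / 1000.0)
    best = None  # (nll, vec, result)
    for attempt in range(options.n_restarts + 1):
        if attempt == 0:
            x0 = theta0
        else:
            jitter = np.exp(0.1 * rng.standard_normal(theta0.size))
            x0 = theta0 * jitter + 0.01 * rng.standard_normal(theta0.size) * (
                np.abs(theta0) < 1e-12
            )
        res = optimize.minimize(
            engine.nll_and_grad,
            x0,
            jac=True,
            method="BFGS",
            options={"gtol": options.gtol, "maxiter": options.max_iter},
        )
        _, grad = engine.nll_and_grad(res.x)
        gnorm = float(np.max(np.abs(grad)))
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, res, gnorm, attempt)
        if gnorm < accept and res.fun < _BIG / 2:
            record = ConvergenceRecord(
                converged=True,
                n_iter=int(res.nit),
                grad_norm=gnorm,
                restarts_used=attempt,
                message=str(res.message),
            )
            return res.x, float(res.fun), record
    nll, vec, res, gnorm, attempt = best
    record = ConvergenceRecord(
        converged=False,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        restarts_used=attempt,
        message=str(res.message),
    )
    return vec, float(nll), record


def _vcov_from_information(H: np.ndarray, names) -> pd.DataFrame:
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("observed information singular; using pseudo-inverse")
        V = np.linalg.pinv(H)
    if np.any(np.diag(V) < 0):
        logger.warning("negative variance in vcov (non-interior optimum?)")
    return pd.DataFrame(V, index=list(names), columns=list(names))


def fit_ml(
    spec: ModelSpec,
    data: pd.DataFrame,
    options: FitOptions | None = None,
    theta0: Mapping[str, float] | None = None,
) -> FittedModel:
    """Maximum-likelihood fit of a single-group model.

    ``data`` must already be on the model scale (log-transformed PET
    columns, centered continuous covariates); :class:`CohortTable`'s
    ``model_frame`` produces it.  Raises :class:`FitError` (carrying the
    best point found) when no restart reaches the gradient tolerance.
    """
    options = options or FitOptions()
    engine = GaussianLikelihood([(spec, data)])
    if engine.n_free > len(data):
        logger.warning(
            "free parameters (%d) exceed subjects (%d)", engine.n_free, len(data)
        )
    start = dict(starting_values(spec, data))
    if theta0:
        start.update({k: float(v) for k, v in theta0.items() if k in engine.index})
    vec0 = engine.vector(start)
    vec, nll, record = _optimize(engine, vec0, options)
    H = engine.observed_information(vec)
    fit = FittedModel(
        spec=spec,
        estimates=engine.as_dict(vec),
        loglik=-nll,
        vcov=_vcov_from_information(H, engine.free_names),
        n=engine.n_total,
        convergence=record,
        information=H,
        engine=engine,
    )
    if not record.converged:
        raise FitError(
            f"optimisation did not converge (|grad|={record.grad_norm:.2e})", best=fit
        )
    return fit


def fit_multigroup(
    group_model: GroupModelSpec,
    data_by_group: Mapping[str, pd.DataFrame],
    options: FitOptions | None = None,
    theta0: Mapping[str, float] | None = None,
) -> MultigroupFit:
    """Joint maximum-likelihood fit of the per-group specs.

    Shared parameters (identical names across groups) are estimated once;
    the joint log-likelihood is the sum of per-group Gaussian blocks.
    """
    options = options or FitOptions()
    blocks = []
    for g in group_model.groups:
        df = data_by_group[g]
        if len(df) == 0:
            raise SpecError(f"group {g!r} has no rows")
        spec = group_model.specs[g]
        if len(df) < len(spec.indicators):
            logger.warning("group %s has fewer rows than indicators", g)
        blocks.append((spec, df))
    engine = GaussianLikelihood(blocks)
    # merge per-group moment starts by averaging over groups
    sums: dict[str, list[float]] = {}
    for (spec, df) in blocks:
        for k, v in starting_values(spec, df).items():
            sums.setdefault(k, []).append(v)
    start = {k: float(np.mean(v)) for k, v in sums.items()}
    if theta0:
        start.update({k: float(v) for k, v in theta0.items() if k in engine.index})
    vec0 = engine.vector(start)
    vec, nll, record = _optimize(engine, vec0, options)
    H = engine.observed_information(vec)
    block_lls = engine.block_nlls(vec)
    fit = MultigroupFit(
        spec=group_model.specs[group_model.groups[0]],
        estimates=engine.as_dict(vec),
        loglik=-nll,
        vcov=_vcov_from_information(H, engine.free_names),
        n=engine.n_total,
        convergence=record,
        information=H,
        engine=engine,
        group_model=group_model,
        group_logliks={
            g: -float(v) for g, v in zip(group_model.groups, block_lls)
        },
    )
    if not record.converged:
        raise FitError(
            f"multigroup optimisation did not converge "
            f"(|grad|={record.grad_norm:.2e})",
            best=fit,
        )
    return fit
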