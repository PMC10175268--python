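"""Group comparisons of demographic, clinical and radiotracer variables.

Continuous variables are compared with Mann-Whitney U tests (exact by
enumeration for small samples, normal approximation with continuity and tie
correction otherwise) and categorical variables with two-sided Fisher exact
tests on 2x2 counts.  The Fisher p-value is computed by explicit
enumeration of the hypergeometric support under the point-probability rule
(sum of all tables with the observed margins whose point probability does
not exceed the observed table's); a tail-doubling variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom, rankdata

from .lvm_spec import GROUPS, CohortTable, SpecError

__all__ = [
    "ContingencyTable2x2",
    "RankTestResult",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "demographics_table",
    "percent",
    "format_p",
]

_EXACT_MW_AUTO = 16  # auto method switches to enumeration at or below this
_EXACT_MW_MAX = 20  # exact method refuses combined samples above this


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns category levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise SpecError("counts must be nonnegative integers")
        if sum(counts) == 0:
            raise SpecError("empty contingency table")


@dataclass(frozen=True)
class RankTestResult:
    u: float  # group-1 convention: U1 = R1 - n1(n1+1)/2 on midranks
    p: float
    method: str  # "exact" | "approx"


def fisher_exact_two_sided(
    table: ContingencyTable2x2 | Sequence[int],
    *,
    rule: str = "point",
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Enumerates the full hypergeometric support of the upper-left cell given
    the margins.  Under the default point-probability rule the p-value sums
    the probabilities of every table no more probable than the observed one;
    ``rule="double"`` instead doubles the smaller tail (capped at 1).
    Returns (conditional odds ratio a*d/(b*c), p); the odds ratio is inf
    when b*c = 0 with a*d > 0.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    if rule == "point":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif rule == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise SpecError(f"unknown two-sided rule {rule!r}")
    p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]))  # midranks
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all labelings: the proportion of
    assignments whose U is at least as far from the null mean n1*n2/2."""
    n = len(pooled_ranks)
    n2 = n - n1
    mid = n1 * n2 / 2.0
    d_obs = abs(u_obs - mid) - 1e-9
    hits = 0
    total = comb(n, n1)
    base = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = pooled_ranks[list(idx)].sum() - base
        if abs(u - mid) >= d_obs:
            hits += 1
    return hits / total


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> RankTestResult:
    """Mann-Whitney U test with midranks for ties.

    ``method="auto"`` enumerates all labelings when the combined sample has
    at most 16 observations, otherwise uses the normal approximation with
    continuity and tie correction.  The exact method refuses combined
    samples above 20 for tractability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise SpecError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if n <= _EXACT_MW_AUTO else "approx"
    if method == "exact":
        if n > _EXACT_MW_MAX:
            raise SpecError(
                f"exact Mann-Whitney refuses combined n > {_EXACT_MW_MAX}"
            )
        ranks = rankdata(np.concatenate([x, y]))
        p = _exact_p(ranks, n1, u)
        return RankTestResult(u, min(1.0, p), "exact")
    if method != "approx":
        raise SpecError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mid = n1 * n2 / 2.0
    if var <= 0:  # complete ties
        return RankTestResult(u, 1.0, "approx")
    # continuity correction toward the null mean
    num = abs(u - mid) - 0.5
    z = max(num, 0.0) / np.sqrt(var)
    p = min(1.0, float(2 * stats.norm.sf(z)))
    return RankTestResult(u, p, "approx")


# ----------------------------------------------------------------- formatting
def percent(k: int, n: int, digits: int = 1) -> float:
    """Percentage of k out of n, rounded for display (78.3 for 108/138)."""
    if n <= 0:
        raise SpecError("percentage denominator must be positive")
    return round(100.0 * k / n, digits)


def format_p(p: float) -> str:
    """Report-style p: below 0.001 prints '<0.001', otherwise 2 significant
    figures (3 when that would round to a boundary like 0.05)."""
    if p < 0.001:
        return "<0.001"
    if p >= 0.995:
        return "1.0"
    s = f"{p:.2g}"
    if float(s) in (0.05,) and p != 0.05:
        s = f"{p:.3g}"
    return s


# ------------------------------------------------------------- demographics table
#: (label, column, kind, positive level) rows mirroring the study's Table 1
#: layout for the variables present in the cohort schema.
DEFAULT_PLAN = (
    ("Age (years)", "age", "continuous", None),
    ("Injected mass (ug/kg)", "inj_mass", "continuous", None),
    ("Females", "sex", "categorical", 1),
    ("5-HTTLPR genotype (LA/LA)", "genotype", "categorical", 0),
)


@dataclass
class DemographicsTable:
    frame: pd.DataFrame
    group_ns: dict[str, int]

    def render_text(self) -> str:
        g1, g2 = GROUPS
        header = (
            f"{'Variable':30s} {g1} (N={self.group_ns[g1]})"
            f"{'':6s}{g2} (N={self.group_ns[g2]}){'':6s}p"
        )
        lines = [header, "-" * len(header)]
        for _, row in self.frame.iterrows():
            if row["kind"] == "continuous":
                cell1 = f"{row[f'{g1}_mean']:.3g} ({row[f'{g1}_sd']:.3g})"
                cell2 = f"{row[f'{g2}_mean']:.3g} ({row[f'{g2}_sd']:.3g})"
            else:
                cell1 = f"{int(row[f'{g1}_n'])} ({row[f'{g1}_pct']:.1f}%)"
                cell2 = f"{int(row[f'{g2}_n'])} ({row[f'{g2}_pct']:.1f}%)"
            lines.append(
                f"{row['variable']:30s} {cell1:20s}{cell2:20s}{format_p(row['p'])}"
            )
        return "\n".join(lines)


def demographics_table(
    cohort: CohortTable, plan: Sequence[tuple] = DEFAULT_PLAN
) -> DemographicsTable:
    """Group comparison table: means/SDs with Mann-Whitney p for continuous
    rows, counts/percentages with Fisher exact p for categorical rows."""
    df = cohort.df
    g1, g2 = GROUPS
    sub = {g: df.loc[df["group"] == g] for g in GROUPS}
    ns = {g: len(sub[g]) for g in GROUPS}
    rows = []
    for label, col, kind, positive in plan:
        if col not in df.columns:
            raise SpecError(f"variable {col!r} absent from cohort")
        row: dict = {"variable": label, "column": col, "kind": kind}
        if kind == "continuous":
            x = sub[g1][col].dropna().to_numpy(float)
            y = sub[g2][col].dropna().to_numpy(float)
            res = mann_whitney_u(x, y)
            row.update(
                {
                    f"{g1}_mean": x.mean(),
                    f"{g1}_sd": x.std(ddof=1),
                    f"{g2}_mean": y.mean(),
                    f"{g2}_sd": y.std(ddof=1),
                    "statistic": res.u,
                    "test": f"mann-whitney ({res.method})",
                    "p": res.p,
                }
            )
        elif kind == "categorical":
            k1 = int((sub[g1][col] == positive).sum())
            k2 = int((sub[g2][col] == positive).sum())
            m1, m2 = ns[g1] - k1, ns[g2] - k2
            odds, p = fisher_exact_two_sided((k1, m1, k2, m2))
            row.update(
                {
                    f"{g1}_n": k1,
                    f"{g1}_pct": percent(k1, ns[g1]),
                    f"{g2}_n": k2,
                    f"{g2}_pct": percent(k2, ns[g2]),
                    "statistic": odds,
                    "test": "fisher exact",
                    "p": p,
                }
            )
        else:
            raise SpecError(f"unknown variable kind {kind!r}")
        rows.append(row)
    return DemographicsTable(frame=pd.DataFrame(rows), group_ns=ns)
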