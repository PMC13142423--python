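"""Tracer-assay arithmetic and the study's rank-based statistics.

Intake, absorption and efficiency derive from body/excreta radiotracer
counts; intake vs time of day is modelled as a quadratic
y = b0 + b1 x + b2 x^2 fit by ordinary least squares.  Group comparisons use
Spearman correlation, the Kruskal-Wallis omnibus test with Dunn's post-hoc
(Holm-adjusted), and the Mann-Whitney U test, with exact small-sample
p-values where enumeration is feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "derive_tracer_measures",
    "QuadraticFit",
    "fit_quadratic",
    "SpearmanResult",
    "spearman",
    "KruskalDunnResult",
    "kruskal_dunn",
    "MannWhitneyResult",
    "mann_whitney",
    "significance_stars",
]

SPEARMAN_EXACT_N = 8
MW_EXACT_TOTAL = 12


def derive_tracer_measures(raw: pd.DataFrame) -> pd.DataFrame:
    """Attach intake, absorption and efficiency to raw body/excreta counts.

    intake = body + excreta; absorption = body; efficiency = body / intake.
    Efficiency is NaN (with ``efficiency_defined`` False) where intake is
    zero; such rows are retained.
    """
    required = {"zt_hr", "group_id", "body_counts", "excreta_counts"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"tracer table missing columns: {sorted(missing)}")
    body = raw["body_counts"].to_numpy(float)
    excreta = raw["excreta_counts"].to_numpy(float)
    if np.any(body < 0) or np.any(excreta < 0):
        raise ValueError("body_counts and excreta_counts must be nonnegative")
    out = raw.copy()
    intake = body + excreta
    out["intake"] = intake
    out["absorption"] = body
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(intake > 0, body / np.where(intake > 0, intake, 1.0), np.nan)
    out["efficiency"] = eff
    out["efficiency_defined"] = intake > 0
    return out


@dataclass
class QuadraticFit:
    """OLS fit of y = b0 + b1 x + b2 x^2 + e."""

    beta: np.ndarray          # (b0, b1, b2)
    se: np.ndarray
    cov: np.ndarray
    resid_var: float
    nobs: int

    @property
    def vertex_hr(self) -> float:
        return -self.beta[1] / (2.0 * self.beta[2])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta[0] + self.beta[1] * x + self.beta[2] * x**2

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(3, 2) array of coefficient confidence bounds (t-based)."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.nobs - 3)
        lo = self.beta - tcrit * self.se
        hi = self.beta + tcrit * self.se
        return np.column_stack([lo, hi])


def fit_quadratic(x, y) -> QuadraticFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values (rank-3 design)")
    X = sm.add_constant(np.column_stack([x, x**2]))
    res = sm.OLS(y, X).fit()
    return QuadraticFit(
        beta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        nobs=int(res.nobs),
    )


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact" or "t-approx"
    degenerate: bool = False


def spearman(x, y) -> SpearmanResult:
    """Spearman correlation with an exact two-sided permutation p for n <= 8.

    rho is the Pearson correlation of mid-ranks.  For larger n the usual
    t-approximation is used.  A constant vector leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=float("nan"), p=float("nan"), n=x.size,
                              method="degenerate", degenerate=True)
    rho, p_approx = stats.spearmanr(x, y)
    n = x.size
    if n <= SPEARMAN_EXACT_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return SpearmanResult(rho=float(rho), p=count / total, n=n, method="exact")
    return SpearmanResult(rho=float(rho), p=float(p_approx), n=n, method="t-approx")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum() / denom)


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_holm


def kruskal_dunn(groups: list[np.ndarray], labels: list[str] | None = None) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis omnibus plus Dunn's pairwise post-hoc
    with Holm adjustment."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        sd = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / sd if sd > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p_raw, 1.0)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return KruskalDunnResult(h=float(h), p=float(p), pairwise=pairwise)


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"
    median_a: float = float("nan")
    median_b: float = float("nan")


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U: exact by enumeration for n1+n2 <= 12
    without ties, tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= MW_EXACT_TOTAL and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return MannWhitneyResult(
        u=float(res.statistic), p=float(res.pvalue), n1=a.size, n2=b.size,
        method=method, median_a=float(np.median(a)), median_b=float(np.median(b)),
    )


def significance_stars(p: float) -> str:
    """The study's convention: * p<0.05, ** p<0.01, *** p<0.001, n.s. otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
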