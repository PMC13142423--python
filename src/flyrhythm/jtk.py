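"""Template-based nonparametric rhythmicity test (JTK_CYCLE style).

The observed series is compared, via Kendall's S, to the rank orderings of
cosine reference waveforms over a grid of circadian periods and phase lags.
The null distribution of S against a fixed (possibly tied) template is
exact: under a uniformly random ordering of the data, S is a shifted
Jonckheere-Terpstra statistic, whose distribution is the convolution of
Mann-Whitney count distributions over sequentially merged template tie
groups.  The reported p-value is a one-sided tail probability for the
maximal S over templates, Bonferroni-corrected by the number of distinct
(deduplicated) templates.

Rank-based throughout: the verdict is invariant under any strictly
monotone transform of the series values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .io_binning import BinnedSeries

__all__ = [
    "JTKConfig",
    "JTKResult",
    "Template",
    "build_templates",
    "kendall_s",
    "null_distribution_s",
    "tail_p",
    "jtk_test",
]

#: Above this series length the exact DP null is replaced by a normal
#: approximation with continuity correction.
EXACT_N_LIMIT = 60

_TIE_DECIMALS = 9  # cosine values closer than 1e-9 are sampling-symmetry ties


@dataclass(frozen=True)
class JTKConfig:
    """Search grid for the rhythmicity test.

    ``period_grid_hr`` defaults to 20-28 h in steps of the bin width; every
    period must exceed twice the sampling interval (Nyquist).  One phase lag
    per sample offset is tested within each period.
    """

    period_grid_hr: tuple[float, ...] | None = None
    waveform: str = "cosine"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.waveform != "cosine":
            raise ValueError(f"only the cosine waveform is supported, got {self.waveform!r}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")

    def periods(self, bin_width_hr: float) -> np.ndarray:
        if self.period_grid_hr is not None:
            grid = np.asarray(self.period_grid_hr, dtype=float)
        else:
            grid = np.arange(20.0, 28.0 + 0.5 * bin_width_hr, bin_width_hr)
        if grid.size == 0:
            raise ValueError("period grid is empty")
        nyquist = 2.0 * bin_width_hr
        if np.any(grid <= nyquist):
            raise ValueError(
                f"all candidate periods must exceed twice the bin width ({nyquist} h)"
            )
        return grid


@dataclass
class Template:
    """One (period, lag) cosine reference reduced to its rank ordering."""

    period_hr: float
    lag_hr: float
    ranks: np.ndarray  # mid-ranks, ties preserved


@dataclass
class JTKResult:
    best_period_hr: float
    best_lag_hr: float
    kendall_s: int
    tau: float
    p_adj: float
    rhythmic: bool
    degenerate: bool = False
    n_templates: int = 0
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "best_period_hr": self.best_period_hr,
            "best_lag_hr": self.best_lag_hr,
            "kendall_s": self.kendall_s,
            "tau": self.tau,
            "p_adj": self.p_adj,
            "rhythmic": self.rhythmic,
            "degenerate": self.degenerate,
            "n_templates": self.n_templates,
            "alpha": self.alpha,
        }


def build_templates(
    timepoints: np.ndarray, bin_width_hr: float, config: JTKConfig
) -> list[Template]:
    """Cosine rank templates over the (period, lag) grid, deduplicated.

    Lags step by the sampling interval within each period; two (period, lag)
    combinations producing the same rank pattern (e.g. lags a period apart)
    collapse to one template, keeping the first (smallest |period-24|, then
    smallest lag) representative.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size < 8:
        raise ValueError(f"need at least 8 timepoints, got {timepoints.size}")
    periods = config.periods(bin_width_hr)
    order = sorted(range(len(periods)), key=lambda i: (abs(periods[i] - 24.0), periods[i]))
    seen: dict[tuple, Template] = {}
    out: list[Template] = []
    for p in periods[order]:
        n_lags = int(math.ceil(p / bin_width_hr - 1e-9))
        for k in range(n_lags):
            lag = k * bin_width_hr
            ref = np.cos(2 * np.pi * (timepoints - lag) / p)
            ref = np.round(ref, _TIE_DECIMALS)
            ranks = stats.rankdata(ref, method="average")
            key = tuple(ranks)
            if key in seen:
                continue
            tpl = Template(period_hr=float(p), lag_hr=float(lag), ranks=ranks)
            seen[key] = tpl
            out.append(tpl)
    return out


def kendall_s(values: np.ndarray, template_ranks: np.ndarray) -> tuple[int, float, int]:
    """Kendall S and tau-a between data values and template ranks.

    S = (#concordant) − (#discordant) over pairs untied in both vectors;
    tau = S / (#pairs untied in both).  Returns ``(S, tau, n_comparable)``;
    tau is NaN when no comparable pair exists (constant data).
    """
    x = np.asarray(values, dtype=float)
    r = np.asarray(template_ranks, dtype=float)
    if x.shape != r.shape or x.size < 2:
        raise ValueError("values and template ranks must be equal-length vectors of size >= 2")
    dx = np.sign(x[:, None] - x[None, :])
    dr = np.sign(r[:, None] - r[None, :])
    prod = dx * dr
    iu = np.triu_indices(x.size, k=1)
    s = int(prod[iu].sum())
    comparable = int(np.count_nonzero((dx[iu] != 0) & (dr[iu] != 0)))
    tau = s / comparable if comparable > 0 else float("nan")
    return s, tau, comparable


@lru_cache(maxsize=4096)
def _mw_counts(m: int, n: int) -> np.ndarray:
    """Orderings of two samples (m, n) counted by the Mann-Whitney statistic
    U (coefficients of the Gaussian binomial [m+n, n]_q).

    Recurrence on the largest element of the pooled sample: if it belongs to
    the size-n sample it exceeds all m others (U shifts by m), otherwise U
    is unchanged.
    """
    if m == 0 or n == 0:
        return np.ones(1)
    out = np.zeros(m * n + 1)
    a = _mw_counts(m, n - 1)
    out[m : m + a.size] += a
    b = _mw_counts(m - 1, n)
    out[: b.size] += b
    return out


def _mw_pmf(m: int, n: int) -> np.ndarray:
    counts = _mw_counts(m, n)
    return counts / counts.sum()


@lru_cache(maxsize=512)
def _jt_pmf(tie_groups: tuple[int, ...]) -> np.ndarray:
    """Exact pmf of the Jonckheere-Terpstra statistic for template tie-group
    sizes ``tie_groups`` (ordered by template rank).

    JT = sum over group pairs k<l of U_{kl}.  Merging groups sequentially,
    the rank placement of each new group among the union of the previous
    ones is independent of the internal arrangement of that union, so the
    pmf is the convolution of Mann-Whitney pmfs U(n_1+...+n_{j-1}, n_j).
    Each factor is normalized before convolving so the result stays at
    machine precision even when the raw ordering counts would overflow.
    """
    pmf = np.ones(1)
    total = 0
    for n_j in tie_groups:
        if total > 0:
            pmf = np.convolve(pmf, _mw_pmf(total, n_j))
        total += n_j
    return pmf


def null_distribution_s(template_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of Kendall S for distinct data against a fixed template.

    Returns ``(s_support, pmf)``: S takes values 2*JT − M where M is the
    number of template-untied pairs.  Requires n <= EXACT_N_LIMIT; larger
    series fall back to :func:`tail_p`'s normal approximation.
    """
    ranks = np.asarray(template_ranks, dtype=float)
    n = ranks.size
    if n > EXACT_N_LIMIT:
        raise ValueError(f"exact null limited to n <= {EXACT_N_LIMIT}, got {n}")
    _, groups = np.unique(np.sort(ranks), return_counts=True)
    pmf = _jt_pmf(tuple(int(g) for g in groups))
    m_pairs = (n * (n - 1) - int(np.sum(groups * (groups - 1)))) // 2
    jt = np.arange(pmf.size)
    support = 2 * jt - m_pairs
    return support, pmf


def _null_moments(template_ranks: np.ndarray) -> tuple[float, float]:
    """Mean (0) and variance of S under the null, for the large-n fallback."""
    ranks = np.asarray(template_ranks, dtype=float)
    n = ranks.size
    _, groups = np.unique(np.sort(ranks), return_counts=True)
    t = groups.astype(float)
    # var(S) for Kendall with ties in one ranking only (Kendall 1970):
    var = (
        n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 18.0
    return 0.0, float(var)


def tail_p(template_ranks: np.ndarray, s_obs: int) -> float:
    """One-sided exact (or large-n approximate) P(S_null >= s_obs)."""
    n = np.asarray(template_ranks).size
    if n <= EXACT_N_LIMIT:
        support, pmf = null_distribution_s(template_ranks)
        return float(pmf[support >= s_obs].sum())
    _, var = _null_moments(template_ranks)
    if var <= 0:
        return 1.0
    # continuity correction: S steps by 2 on tie-free support
    z = (s_obs - 1.0) / math.sqrt(var)
    return float(stats.norm.sf(z))


def jtk_test(series: BinnedSeries, config: JTKConfig | None = None) -> JTKResult:
    """Run the rhythmicity test on a regularly sampled binned series.

    The maximal Kendall S over all deduplicated (period, lag) templates is
    referred to its exact null; the p-value is Bonferroni-adjusted by the
    template count.  Ties in S are broken toward |period − 24| and then the
    smaller lag (the templates are searched in that order).  A constant
    series is degenerate: reported non-rhythmic with p_adj = 1.
    """
    config = config or JTKConfig()
    t = series.bin_center_hr
    if len(series) >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("series must be regularly sampled")
    periods = config.periods(series.bin_width_hr)
    span = t[-1] - t[0] + series.bin_width_hr if len(series) else 0.0
    if span < float(np.min(periods)):
        raise ValueError(
            f"series span {span:.1f} h is shorter than the smallest candidate period"
        )
    templates = build_templates(t, series.bin_width_hr, config)

    values = series.value
    if np.all(values == values[0]):
        return JTKResult(
            best_period_hr=float("nan"), best_lag_hr=float("nan"), kendall_s=0,
            tau=float("nan"), p_adj=1.0, rhythmic=False, degenerate=True,
            n_templates=len(templates), alpha=config.alpha,
        )

    best: Template | None = None
    best_s = None
    best_tau = float("nan")
    for tpl in templates:  # already ordered by |period-24| then lag
        s, tau, _ = kendall_s(values, tpl.ranks)
        if best_s is None or s > best_s:
            best, best_s, best_tau = tpl, s, tau
    p1 = tail_p(best.ranks, best_s)
    p_adj = min(1.0, len(templates) * p1)
    return JTKResult(
        best_period_hr=best.period_hr,
        best_lag_hr=best.lag_hr,
        kendall_s=int(best_s),
        tau=best_tau,
        p_adj=p_adj,
        rhythmic=p_adj < config.alpha,
        degenerate=False,
        n_templates=len(templates),
        alpha=config.alpha,
    )
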