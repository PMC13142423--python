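"""Clock-reporter quantification from per-cell intensity tables.

Enterocyte (EC) mode: per-cell deltaF = F_nucleus - F_cytoplasm summarizes
nuclear CLK/CYC-driven reporter activity; timepoints are compared per midgut
region with the Mann-Whitney U test, with the gut (cells averaged within a
gut) as the statistical unit to avoid pseudo-replication.

Enteroendocrine (EEC) mode: individual signals are faint, so clock activity
is read out as the per-gut count of reporter-positive cells — nuclear
intensity strictly above background_mean + k * background_sd — and the
counts at two timepoints are compared with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import MIDGUT_REGIONS
from .tracer_stats import MannWhitneyResult, mann_whitney, significance_stars

__all__ = [
    "PositivityRule",
    "delta_f",
    "region_timepoint_compare",
    "count_clk_positive",
    "positivity_oscillation_test",
]

REPORTER_COLUMNS = [
    "gut_id", "region", "cell_id", "timepoint_hr", "f_nucleus", "f_cytoplasm", "cell_type",
]


@dataclass(frozen=True)
class PositivityRule:
    """Positive means nuclear intensity strictly above mean + k*SD of the
    gut's epithelial background (a numeric surrogate for the visual
    'clearly above local background' criterion)."""

    background: pd.DataFrame  # gut_id, background_mean, background_sd
    k: float = 2.0

    def __post_init__(self) -> None:
        required = {"gut_id", "background_mean", "background_sd"}
        missing = required - set(self.background.columns)
        if missing:
            raise ValueError(f"background stats missing columns: {sorted(missing)}")
        if (self.background["background_sd"] <= 0).any():
            raise ValueError("background_sd must be > 0 for every gut")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")

    def threshold_for(self, gut_ids: pd.Series) -> np.ndarray:
        thr = self.background.set_index("gut_id")
        missing = set(gut_ids.unique()) - set(thr.index)
        if missing:
            raise ValueError(f"no background statistics for guts: {sorted(missing)}")
        vals = thr.loc[gut_ids, "background_mean"] + self.k * thr.loc[gut_ids, "background_sd"]
        return vals.to_numpy(float)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REPORTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reporter table missing columns: {missing}")


def delta_f(table: pd.DataFrame) -> pd.DataFrame:
    """Attach per-cell deltaF = f_nucleus - f_cytoplasm (may be negative)."""
    _check_table(table)
    if table[["f_nucleus", "f_cytoplasm"]].isna().any().any():
        raise ValueError("missing intensity values in reporter table")
    out = table.copy()
    out["delta_f"] = out["f_nucleus"] - out["f_cytoplasm"]
    return out


def region_timepoint_compare(
    table: pd.DataFrame,
    t1: float,
    t2: float,
    regions: tuple[str, ...] = MIDGUT_REGIONS,
) -> pd.DataFrame:
    """Per-region Mann-Whitney comparison of deltaF between two timepoints.

    Cells are averaged within each gut; guts are the samples.  Returns one
    row per region with n per timepoint, U, p, significance stars, and the
    per-gut mean deltaF at each timepoint.
    """
    tab = delta_f(table[table["cell_type"] == "EC"]) if "delta_f" not in table.columns else table
    rows = []
    for region in regions:
        sub = tab[tab["region"] == region]
        per_gut = (
            sub[sub["timepoint_hr"].isin([t1, t2])]
            .groupby(["timepoint_hr", "gut_id"])["delta_f"]
            .mean()
        )
        for t in (t1, t2):
            if t not in sub["timepoint_hr"].unique():
                raise ValueError(f"timepoint {t} absent in region {region}")
        a = per_gut.loc[t1].to_numpy(float)
        b = per_gut.loc[t2].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"region {region} has fewer than 2 guts at a timepoint")
        res = mann_whitney(a, b)
        rows.append(
            {
                "region": region,
                "n_t1": a.size,
                "n_t2": b.size,
                "mean_delta_f_t1": float(a.mean()),
                "mean_delta_f_t2": float(b.mean()),
                "U": res.u,
                "p": res.p,
                "stars": significance_stars(res.p),
            }
        )
    return pd.DataFrame(rows)


def count_clk_positive(table: pd.DataFrame, rule: PositivityRule) -> pd.DataFrame:
    """Per-gut, per-timepoint count of reporter-positive cells
    (strict inequality at the threshold)."""
    _check_table(table)
    tab = table.copy()
    tab["_thr"] = rule.threshold_for(tab["gut_id"])
    tab["_pos"] = tab["f_nucleus"] > tab["_thr"]
    counts = (
        tab.groupby(["gut_id", "timepoint_hr"], as_index=False)["_pos"]
        .sum()
        .rename(columns={"_pos": "n_positive"})
    )
    counts["n_positive"] = counts["n_positive"].astype(int)
    return counts


def positivity_oscillation_test(
    counts: pd.DataFrame, t1: float, t2: float
) -> dict:
    """Mann-Whitney comparison of per-gut positive-cell counts at two
    timepoints; reports medians and the direction of the difference."""
    for col in ("timepoint_hr", "n_positive"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col}")
    a = counts.loc[counts["timepoint_hr"] == t1, "n_positive"].to_numpy(float)
    b = counts.loc[counts["timepoint_hr"] == t2, "n_positive"].to_numpy(float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 guts per timepoint")
    res: MannWhitneyResult = mann_whitney(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "t1>t2"
    elif med_a < med_b:
        direction = "t1<t2"
    else:
        direction = "t1=t2"
    return {
        "U": res.u,
        "p": res.p,
        "stars": significance_stars(res.p),
        "median_t1": med_a,
        "median_t2": med_b,
        "direction": direction,
        "n_t1": int(a.size),
        "n_t2": int(b.size),
    }
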