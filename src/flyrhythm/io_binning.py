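"""Event-log I/O and conversion to population-mean binned feeding series.

The recorder's day starts at lights-on; the first ``gap_hr`` hours of each
day (capillary change + re-acclimation) are excluded, and the remaining
~23.5-h recording span is tiled by twelve equal bins.  Bin centers are
reported on the nominal uniform grid (2-h spacing at defaults) so the series
is regularly spaced, as the downstream rhythm analyses require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import FeedingEventLog

__all__ = ["BinnedSeries", "read_event_log", "write_event_log", "bin_events", "select_window"]

EVENT_COLUMNS = ["fly_id", "time_hr", "volume_uL"]


@dataclass
class BinnedSeries:
    """Population-mean intake per bin with light-regime annotation.

    ``value`` is mean intake per fly per bin (µL): the summed volume of all
    events in the bin divided by the number of flies in the experiment
    (including flies that never fed — a per-capita rate).
    """

    bin_center_hr: np.ndarray
    value: np.ndarray
    regime: np.ndarray
    n_flies: int
    bin_width_hr: float

    def __post_init__(self) -> None:
        self.bin_center_hr = np.asarray(self.bin_center_hr, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.regime = np.asarray(self.regime, dtype=object)
        if not (len(self.bin_center_hr) == len(self.value) == len(self.regime)):
            raise ValueError("bin_center_hr, value and regime must have equal length")

    def __len__(self) -> int:
        return len(self.value)

    @property
    def regime_day(self) -> np.ndarray:
        """1-based day index within each bin's regime run (LD1, LD2, DD1, ...)."""
        bins_per_day = int(round(24.0 / self.bin_width_hr))
        day = np.arange(len(self)) // bins_per_day
        out = np.zeros(len(self), dtype=int)
        day_regimes = [self.regime[d * bins_per_day] for d in range(len(self) // bins_per_day)]
        counter: dict[str, int] = {}
        day_number = []
        for r in day_regimes:
            counter[r] = counter.get(r, 0) + 1
            day_number.append(counter[r])
        for i in range(len(self)):
            out[i] = day_number[day[i]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_hr": self.bin_center_hr,
                "value_uL": self.value,
                "regime": self.regime,
                "n_flies": self.n_flies,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bin_width_hr: float | None = None) -> "BinnedSeries":
        df = pd.read_csv(path)
        required = {"bin_center_hr", "value_uL", "regime", "n_flies"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"binned series file missing columns: {sorted(missing)}")
        centers = df["bin_center_hr"].to_numpy(float)
        if bin_width_hr is None:
            diffs = np.diff(centers)
            bin_width_hr = float(np.median(diffs)) if len(diffs) else 2.0
        return cls(
            bin_center_hr=centers,
            value=df["value_uL"].to_numpy(float),
            regime=df["regime"].to_numpy(object),
            n_flies=int(df["n_flies"].iloc[0]),
            bin_width_hr=bin_width_hr,
        )


def read_event_log(
    path,
    fly_ids: tuple[str, ...] | None = None,
    day_regimes: tuple[str, ...] | None = None,
    recording_gap_hr: float = 0.5,
) -> FeedingEventLog:
    """Read an event-log CSV (``fly_id,time_hr,volume_uL``).

    ``fly_ids`` and ``day_regimes`` carry the experiment metadata the flat
    file cannot; by default flies are inferred from the file and every
    recorded day is labelled DD.
    """
    df = pd.read_csv(path, dtype={"fly_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log {path} missing columns: {missing}")
    for col in ("time_hr", "volume_uL"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if df[col].isna().any():
            bad = np.append(bad, np.nonzero(df[col].isna().to_numpy())[0])
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"non-numeric {col} at row {int(bad.min()) + 2} of {path}")
        df[col] = vals
    neg_t = np.nonzero((df["time_hr"] < 0).to_numpy())[0]
    if neg_t.size:
        raise ValueError(f"negative time_hr at row {int(neg_t[0]) + 2} of {path}")
    bad_v = np.nonzero((df["volume_uL"] <= 0).to_numpy())[0]
    if bad_v.size:
        raise ValueError(f"non-positive volume_uL at row {int(bad_v[0]) + 2} of {path}")
    df = df.sort_values(["fly_id", "time_hr"], kind="stable").reset_index(drop=True)
    if fly_ids is None:
        fly_ids = tuple(sorted(df["fly_id"].unique()))
    if day_regimes is None:
        last = float(df["time_hr"].max()) if len(df) else 0.0
        n_days = max(int(np.ceil(last / 24.0)), 1)
        day_regimes = ("DD",) * n_days
    return FeedingEventLog(
        events=df[EVENT_COLUMNS],
        fly_ids=tuple(fly_ids),
        day_regimes=tuple(day_regimes),
        recording_gap_hr=recording_gap_hr,
    )


def write_event_log(log: FeedingEventLog, path) -> None:
    df = log.events.sort_values(["fly_id", "time_hr"], kind="stable")
    df.to_csv(path, index=False, columns=EVENT_COLUMNS)


def _bins_per_day(bin_width_hr: float) -> int:
    n = 24.0 / bin_width_hr
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"bin_width_hr={bin_width_hr} does not tile the day: 24/bin_width must be an integer"
        )
    return int(round(n))


def bin_events(
    log: FeedingEventLog,
    bin_width_hr: float = 2.0,
    gap_hr: float | None = None,
) -> BinnedSeries:
    """Bin events into the population-mean intake series.

    Each day contributes ``24/bin_width_hr`` bins; the recording span
    (24 − gap) is tiled by bins of equal actual width, while reported
    centers lie on the nominal uniform grid ``day_start + gap +
    (j + 1/2) * bin_width``.  Events inside the daily gap are dropped; bins
    are half-open [start, end), so an event exactly at the gap boundary
    belongs to the first bin.
    """
    if gap_hr is None:
        gap_hr = log.recording_gap_hr
    if not (0 <= gap_hr < 24):
        raise ValueError(f"gap_hr must lie in [0, 24), got {gap_hr}")
    n_per_day = _bins_per_day(bin_width_hr)
    actual_width = (24.0 - gap_hr) / n_per_day
    n_days = log.n_days
    n_bins = n_per_day * n_days

    t = log.events["time_hr"].to_numpy(float)
    v = log.events["volume_uL"].to_numpy(float)
    if t.size and t.max() >= 24.0 * n_days:
        raise ValueError(
            f"event at {t.max():.3f} h falls outside the {n_days}-day experiment"
        )
    day = np.floor(t / 24.0).astype(int)
    tod = t - 24.0 * day
    keep = tod >= gap_hr
    idx = day[keep] * n_per_day + np.floor((tod[keep] - gap_hr) / actual_width).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # guard float roundoff at the last edge
    totals = np.bincount(idx, weights=v[keep], minlength=n_bins)

    day_of_bin = np.arange(n_bins) // n_per_day
    j = np.arange(n_bins) % n_per_day
    centers = 24.0 * day_of_bin + gap_hr + (j + 0.5) * bin_width_hr
    regime = np.array([log.day_regimes[d] for d in day_of_bin], dtype=object)
    return BinnedSeries(
        bin_center_hr=centers,
        value=totals / log.n_flies,
        regime=regime,
        n_flies=log.n_flies,
        bin_width_hr=bin_width_hr,
    )


def select_window(series: BinnedSeries, regime: str, day_range: tuple[int, int]) -> BinnedSeries:
    """Contiguous sub-series covering days ``day_range`` (1-based, inclusive)
    of the requested regime; the time origin is preserved."""
    lo, hi = day_range
    if lo < 1 or hi < lo:
        raise ValueError(f"day_range must satisfy 1 <= lo <= hi, got {day_range}")
    rd = series.regime_day
    mask = (series.regime == regime) & (rd >= lo) & (rd <= hi)
    present_days = set(rd[series.regime == regime].tolist())
    wanted = set(range(lo, hi + 1))
    if not wanted <= present_days:
        raise ValueError(
            f"requested {regime} days {sorted(wanted - present_days)} not present in series"
        )
    idx = np.nonzero(mask)[0]
    if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
        raise ValueError("requested window is not contiguous in the series")
    return BinnedSeries(
        bin_center_hr=series.bin_center_hr[idx],
        value=series.value[idx],
        regime=series.regime[idx],
        n_flies=series.n_flies,
        bin_width_hr=series.bin_width_hr,
    )
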