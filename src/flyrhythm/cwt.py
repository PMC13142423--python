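"""Time-resolved wavelet analysis of binned feeding series.

A continuous wavelet transform with the analytic Morlet wavelet
(center frequency omega0, default 6) decomposes the series into a
time x period power scalogram over a circadian band.  Per timepoint, the
period of maximal power is the *dominant period* (the ridge); power along
the ridge, normalized to the maximum across groups of its time-mean,
is the *rhythm-strength curve* used for cross-group comparison.

Implementation notes: the transform is computed in the frequency domain
with unit-energy scale normalization sqrt(2 pi s / dt) and zero padding;
scale converts to Fourier period via 4 pi s / (omega0 + sqrt(2 + omega0^2)),
and the cone of influence uses the sqrt(2) s e-folding time.  With this
normalization the power argmax over scale for a pure sinusoid falls exactly
at the sinusoid's period on the period axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_binning import BinnedSeries

__all__ = [
    "CWTConfig",
    "Scalogram",
    "DominantRidge",
    "StrengthCurve",
    "compute_cwt",
    "extract_dominant_ridge",
    "strength_curves",
    "damping_summary",
]

RIDGE_POWER_FLOOR = 1e-12  # x global max: below this, a timepoint has no dominant rhythm
LOG_STRENGTH_EPS = 1e-9


@dataclass(frozen=True)
class CWTConfig:
    wavelet: str = "morlet"
    omega0: float = 6.0
    period_band_hr: tuple[float, float] = (16.0, 32.0)
    n_scales: int = 64
    detrend: str = "mean"

    def __post_init__(self) -> None:
        if self.wavelet != "morlet":
            raise ValueError(f"only the Morlet wavelet is supported, got {self.wavelet!r}")
        if self.n_scales < 8:
            raise ValueError(f"n_scales must be >= 8, got {self.n_scales}")
        lo, hi = self.period_band_hr
        if not (0 < lo < hi):
            raise ValueError(f"period band must satisfy 0 < min < max, got {self.period_band_hr}")
        if self.detrend not in ("mean", "linear"):
            raise ValueError(f"detrend must be 'mean' or 'linear', got {self.detrend!r}")

    @property
    def fourier_factor(self) -> float:
        return 4 * math.pi / (self.omega0 + math.sqrt(2 + self.omega0**2))

    def periods(self) -> np.ndarray:
        lo, hi = self.period_band_hr
        return np.exp(np.linspace(math.log(lo), math.log(hi), self.n_scales))


@dataclass
class Scalogram:
    """Wavelet power over time x period, with a cone-of-influence mask
    (True = edge-unreliable)."""

    time_hr: np.ndarray
    period_hr: np.ndarray
    power: np.ndarray  # shape (n_times, n_periods), >= 0
    coi_mask: np.ndarray  # same shape, boolean

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = [f"{p:.6g}" for p in self.period_hr]
        power = pd.DataFrame(self.power, columns=cols)
        power.insert(0, "time_hr", self.time_hr)
        mask = pd.DataFrame(self.coi_mask.astype(int), columns=cols)
        mask.insert(0, "time_hr", self.time_hr)
        return power, mask


@dataclass
class DominantRidge:
    time_hr: np.ndarray
    period_hr: np.ndarray  # dominant period per timepoint
    power: np.ndarray      # power along the ridge
    valid: np.ndarray      # False where band power is below the floor
    in_coi: np.ndarray     # True where the ridge point is edge-unreliable


@dataclass
class StrengthCurve:
    time_hr: np.ndarray
    strength: np.ndarray
    valid: np.ndarray      # valid ridge AND outside the cone of influence
    norm_constant: float
    group: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.time_hr,
                "strength": self.strength,
                "valid": self.valid.astype(int),
                "group": self.group,
            }
        )


def compute_cwt(series: BinnedSeries, config: CWTConfig | None = None) -> Scalogram:
    """Morlet power scalogram of a regularly sampled series.

    The detrended series is zero-padded to the next power of two and
    convolved in the frequency domain with unit-energy analytic Morlet
    wavelets at log-spaced scales spanning the period band.
    """
    config = config or CWTConfig()
    x = np.asarray(series.value, dtype=float)
    t = np.asarray(series.bin_center_hr, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains NaN or infinite values")
    n = x.size
    dt = series.bin_width_hr
    if n < 2:
        raise ValueError("series too short for wavelet analysis")
    band_max = config.period_band_hr[1]
    if n * dt < band_max:
        raise ValueError(
            f"series spans {n * dt:.1f} h, shorter than the band maximum period {band_max} h"
        )

    if config.detrend == "mean":
        x = x - x.mean()
    else:
        coef = np.polyfit(t, x, 1)
        x = x - np.polyval(coef, t)

    n_pad = 1 << max(int(math.ceil(math.log2(n))) + 1, 2)
    xf = np.fft.fft(x, n_pad)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    periods = config.periods()
    scales = periods / config.fourier_factor
    power = np.empty((n, periods.size))
    norm_const = math.pi ** -0.25
    for k, s in enumerate(scales):
        psi_hat = np.where(
            omega > 0,
            norm_const * math.sqrt(2 * math.pi * s / dt) * np.exp(-0.5 * (s * omega - config.omega0) ** 2),
            0.0,
        )
        w = np.fft.ifft(xf * psi_hat)[:n]
        power[:, k] = np.abs(w) ** 2

    # cone of influence: within sqrt(2)*s of either edge, power is unreliable
    dist_edge = np.minimum(t - t[0], t[-1] - t) + dt / 2.0
    efold = math.sqrt(2.0) * scales
    coi_mask = efold[None, :] > dist_edge[:, None]
    return Scalogram(time_hr=t, period_hr=periods, power=power, coi_mask=coi_mask)


def extract_dominant_ridge(scal: Scalogram) -> DominantRidge:
    """Per timepoint, the period of maximal power within the band.

    Ties (within floating tolerance) break toward the period closest to
    24 h.  Timepoints whose maximal power falls below ``RIDGE_POWER_FLOOR``
    times the global maximum carry no dominant rhythm and are flagged
    invalid.
    """
    power = scal.power
    if power.size == 0:
        raise ValueError("empty scalogram")
    global_max = power.max()
    floor = RIDGE_POWER_FLOOR * global_max
    n_t = power.shape[0]
    ridge_period = np.empty(n_t)
    ridge_power = np.empty(n_t)
    valid = np.empty(n_t, dtype=bool)
    in_coi = np.empty(n_t, dtype=bool)
    dist24 = np.abs(scal.period_hr - 24.0)
    for i in range(n_t):
        row = power[i]
        m = row.max()
        near = row >= m * (1 - 1e-12)
        cand = np.nonzero(near)[0]
        k = cand[np.argmin(dist24[cand])]
        ridge_period[i] = scal.period_hr[k]
        ridge_power[i] = row[k]
        valid[i] = m > floor
        in_coi[i] = bool(scal.coi_mask[i, k])
    return DominantRidge(
        time_hr=scal.time_hr, period_hr=ridge_period, power=ridge_power,
        valid=valid, in_coi=in_coi,
    )


def strength_curves(
    scalograms: dict[str, Scalogram], stat: str = "mean"
) -> dict[str, StrengthCurve]:
    """Jointly normalized rhythm-strength curves for a set of groups.

    Raw strength is power along each group's dominant ridge; the shared
    normalization constant G is the max over groups of the time-``stat``
    (mean by default, max as the alternative reading) of raw strength over
    valid, edge-reliable timepoints.  Every curve is divided by G, so the
    max over groups of the time-mean normalized strength is 1 under the
    default.
    """
    if not scalograms:
        raise ValueError("need at least one group")
    if stat not in ("mean", "max"):
        raise ValueError(f"stat must be 'mean' or 'max', got {stat!r}")
    ridges = {g: extract_dominant_ridge(s) for g, s in scalograms.items()}
    time_axes = [s.time_hr for s in scalograms.values()]
    for ta in time_axes[1:]:
        if not np.array_equal(ta, time_axes[0]):
            raise ValueError("group scalograms must share an aligned time axis")
    group_stat = {}
    for g, r in ridges.items():
        ok = r.valid & ~r.in_coi
        if ok.any():
            group_stat[g] = float(r.power[ok].mean() if stat == "mean" else r.power[ok].max())
    if not group_stat:
        raise ValueError("all groups are entirely invalid (no reliable ridge power)")
    norm = max(group_stat.values())
    if norm <= 0:
        raise ValueError("normalization constant is zero: no rhythmic power in any group")
    return {
        g: StrengthCurve(
            time_hr=r.time_hr,
            strength=r.power / norm,
            valid=r.valid & ~r.in_coi,
            norm_constant=norm,
            group=g,
        )
        for g, r in ridges.items()
    }


def damping_summary(curve: StrengthCurve) -> float:
    """Least-squares slope (1/hr) of log(strength + eps) vs time over the
    curve's valid timepoints.

    For a rhythm whose amplitude decays as exp(-gamma t), wavelet power
    decays as exp(-2 gamma t), so the returned slope estimates -2 gamma.
    """
    ok = curve.valid
    if int(ok.sum()) < 6:
        raise ValueError(f"need >= 6 valid timepoints, got {int(ok.sum())}")
    y = np.log(curve.strength[ok] + LOG_STRENGTH_EPS)
    slope = np.polyfit(curve.time_hr[ok], y, 1)[0]
    return float(slope)
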