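"""Synthetic experiment generators for circadian feeding studies.

This module is the in-silico stand-in for three laboratory assays:

* an ARC-style (Automated Recording CAFE) feeding recorder producing per-fly
  timestamped meal events, simulated as an exact inhomogeneous Poisson
  process via thinning;
* a radiotracer intake/absorption assay producing per-group body and excreta
  counts at a set of Zeitgeber times;
* confocal quantification of a nuclear clock reporter, producing per-cell
  nuclear/cytoplasmic intensity tables (enterocyte mode) or positivity-count
  structure (enteroendocrine mode).

Every generator is a pure function of its config (including the seed): the
same config yields a bit-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeedingScenarioConfig",
    "FeedingEventLog",
    "TracerScenarioConfig",
    "TracerTable",
    "ReporterScenarioConfig",
    "simulate_feeding_events",
    "simulate_tracer_assay",
    "simulate_reporter_cells",
    "FEEDING_SCENARIOS",
    "scenario_config",
    "MIDGUT_REGIONS",
]

MIDGUT_REGIONS = ("R1", "R2", "R3", "R4", "R5")


def _check_finite_nonneg(name: str, value: float, allow_zero: bool = True) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0 or (not allow_zero and value == 0):
        kind = "nonnegative" if allow_zero else "positive"
        raise ValueError(f"{name} must be {kind}, got {value!r}")


@dataclass(frozen=True)
class FeedingScenarioConfig:
    """Design of one simulated ARC feeding experiment.

    Times are hours since lights-on of day 1.  Entrainment days run under LD;
    free-running days under ``regime_free`` (DD or LL).  The per-fly event
    rate is

        lambda_i(t) = b_i * baseline_rate * max(0, 1 + A(t) cos(2 pi (t - phi(t)) / period_hr))

    with b_i a lognormal fly-effect multiplier, A(t) = rel_amplitude during
    entrainment and rel_amplitude * exp(-damping_rate * t_free) during
    free-run, and phi(t) the acrophase — fixed, except under LL where it
    performs a Gaussian random walk across free-running days (one shared walk
    for the whole population).  The rate is masked to zero inside the daily
    recording gap and inside any fasting window.
    """

    n_flies: int = 30
    days_entrain: int = 3
    days_free: int = 3
    regime_free: str = "DD"
    bin_width_hr: float = 2.0
    recording_gap_hr: float = 0.5
    baseline_rate: float = 1.5        # events / hr / fly
    rel_amplitude: float = 0.6
    period_hr: float = 24.0
    acrophase_hr: float = 1.0         # peak intake, hours after lights-on
    damping_rate: float = 0.0         # 1/hr amplitude decay during free-run
    phase_diffusion_sd_hr: float = 0.0  # per-day phase walk SD (LL only)
    fly_effect_sd: float = 0.3        # log-scale SD of per-fly multiplier
    meal_mean_uL: float = 0.02
    meal_shape: float = 2.0
    fasting_schedule: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError(f"n_flies must be positive, got {self.n_flies}")
        if self.days_entrain < 0 or self.days_free < 0:
            raise ValueError("days_entrain and days_free must be >= 0")
        if self.regime_free not in ("DD", "LL"):
            raise ValueError(f"regime_free must be 'DD' or 'LL', got {self.regime_free!r}")
        _check_finite_nonneg("bin_width_hr", self.bin_width_hr, allow_zero=False)
        _check_finite_nonneg("recording_gap_hr", self.recording_gap_hr)
        _check_finite_nonneg("baseline_rate", self.baseline_rate)
        if not np.isfinite(self.rel_amplitude) or not (0.0 <= self.rel_amplitude <= 1.0):
            raise ValueError(f"rel_amplitude must lie in [0, 1], got {self.rel_amplitude!r}")
        _check_finite_nonneg("period_hr", self.period_hr, allow_zero=False)
        if not np.isfinite(self.acrophase_hr):
            raise ValueError(f"acrophase_hr must be finite, got {self.acrophase_hr!r}")
        _check_finite_nonneg("damping_rate", self.damping_rate)
        _check_finite_nonneg("phase_diffusion_sd_hr", self.phase_diffusion_sd_hr)
        _check_finite_nonneg("fly_effect_sd", self.fly_effect_sd)
        _check_finite_nonneg("meal_mean_uL", self.meal_mean_uL, allow_zero=False)
        _check_finite_nonneg("meal_shape", self.meal_shape, allow_zero=False)
        if self.fasting_schedule is not None:
            sched = tuple(tuple(map(float, w)) for w in self.fasting_schedule)
            for start, end in sched:
                if not (0 <= start < end <= 24):
                    raise ValueError(
                        f"fasting_schedule windows must satisfy 0 <= start < end <= 24, got {(start, end)}"
                    )
            object.__setattr__(self, "fasting_schedule", sched)

    @property
    def n_days(self) -> int:
        return self.days_entrain + self.days_free

    @property
    def total_hr(self) -> float:
        return 24.0 * self.n_days

    @property
    def day_regimes(self) -> tuple[str, ...]:
        return ("LD",) * self.days_entrain + (self.regime_free,) * self.days_free


@dataclass
class FeedingEventLog:
    """Per-fly timestamped meal events plus scenario metadata.

    ``events`` has columns ``fly_id, time_hr, volume_uL``; ``fly_ids`` lists
    every fly in the experiment (including flies that never fed), which is
    what the per-capita population mean divides by.
    """

    events: pd.DataFrame
    fly_ids: tuple[str, ...]
    day_regimes: tuple[str, ...]
    recording_gap_hr: float = 0.5

    @property
    def n_flies(self) -> int:
        return len(self.fly_ids)

    @property
    def n_days(self) -> int:
        return len(self.day_regimes)


def _rate_modifiers(config: FeedingScenarioConfig, t: np.ndarray, phase_walk: np.ndarray) -> np.ndarray:
    """Fly-independent part of the rate: max(0, 1 + A(t) cos(...)), with masking."""
    t = np.asarray(t, dtype=float)
    t_entrain_end = 24.0 * config.days_entrain
    amp = np.where(
        t < t_entrain_end,
        config.rel_amplitude,
        config.rel_amplitude * np.exp(-config.damping_rate * np.maximum(t - t_entrain_end, 0.0)),
    )
    day = np.minimum(np.floor(t / 24.0).astype(int), config.n_days - 1)
    phi = np.full_like(t, config.acrophase_hr)
    if config.regime_free == "LL" and config.days_free > 0:
        free_day = day - config.days_entrain
        in_free = free_day >= 0
        phi = np.where(in_free, config.acrophase_hr + phase_walk[np.maximum(free_day, 0)], phi)
    mod = np.maximum(0.0, 1.0 + amp * np.cos(2 * np.pi * (t - phi) / config.period_hr))
    tod = np.mod(t, 24.0)
    mod = np.where(tod < config.recording_gap_hr, 0.0, mod)
    if config.fasting_schedule:
        for start, end in config.fasting_schedule:
            mod = np.where((tod >= start) & (tod < end), 0.0, mod)
    return mod


def simulate_feeding_events(config: FeedingScenarioConfig) -> FeedingEventLog:
    """Simulate an ARC feeding experiment as an exact inhomogeneous Poisson process.

    Uses thinning (rejection) against the bound b_i * baseline_rate *
    (1 + rel_amplitude), so event times follow the continuous-time rate
    exactly rather than a discretized approximation.  Meal volumes are i.i.d.
    gamma(meal_shape, meal_mean_uL / meal_shape).
    """
    rng = np.random.default_rng(config.seed)
    # Shared population phase walk under LL (one step per free-running day).
    if config.regime_free == "LL" and config.days_free > 0 and config.phase_diffusion_sd_hr > 0:
        steps = rng.normal(0.0, config.phase_diffusion_sd_hr, size=config.days_free)
        phase_walk = np.cumsum(steps)
    else:
        phase_walk = np.zeros(max(config.days_free, 1))

    total_hr = config.total_hr
    lam_bound_mod = 1.0 + config.rel_amplitude
    fly_ids, times, volumes = [], [], []
    for i in range(config.n_flies):
        fid = f"fly{i + 1:03d}"
        b_i = rng.lognormal(mean=0.0, sigma=config.fly_effect_sd) if config.fly_effect_sd > 0 else 1.0
        lam_max = b_i * config.baseline_rate * lam_bound_mod
        n_cand = rng.poisson(lam_max * total_hr)
        cand = np.sort(rng.uniform(0.0, total_hr, size=n_cand))
        u = rng.uniform(size=n_cand)
        accept = u * lam_bound_mod < _rate_modifiers(config, cand, phase_walk)
        t_acc = cand[accept]
        v = rng.gamma(config.meal_shape, config.meal_mean_uL / config.meal_shape, size=t_acc.size)
        fly_ids.append(np.full(t_acc.size, fid))
        times.append(t_acc)
        volumes.append(v)

    events = pd.DataFrame(
        {
            "fly_id": np.concatenate(fly_ids) if fly_ids else np.array([], dtype=object),
            "time_hr": np.concatenate(times) if times else np.array([], dtype=float),
            "volume_uL": np.concatenate(volumes) if volumes else np.array([], dtype=float),
        }
    )
    return FeedingEventLog(
        events=events,
        fly_ids=tuple(f"fly{i + 1:03d}" for i in range(config.n_flies)),
        day_regimes=config.day_regimes,
        recording_gap_hr=config.recording_gap_hr,
    )


# ---------------------------------------------------------------------------
# Tracer assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerScenarioConfig:
    """Design of one simulated radiotracer intake/absorption assay.

    The true group intake at Zeitgeber time x is the U-shaped quadratic
    c0 + c1 x + c2 x^2 (c2 > 0) scaled by lognormal group noise; a truncated-
    normal absorption efficiency in (0, 1] splits intake into body counts
    (absorbed) and excreta counts (the remainder).
    """

    n_groups_per_time: int = 5
    flies_per_group: int = 10
    zt_times: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    intake_coeffs: tuple[float, float, float] = (3000.0, -360.0, 15.0)
    efficiency_mean: float = 0.75
    efficiency_sd: float = 0.05
    group_noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups_per_time < 1 or self.flies_per_group < 1:
            raise ValueError("n_groups_per_time and flies_per_group must be >= 1")
        if len(self.zt_times) < 3:
            raise ValueError("need at least 3 Zeitgeber times")
        if self.intake_coeffs[2] <= 0:
            raise ValueError(
                f"intake_coeffs c2 must be > 0 (U-shaped intake), got {self.intake_coeffs[2]!r}"
            )
        if not (0 < self.efficiency_mean <= 1):
            raise ValueError(f"efficiency_mean must lie in (0, 1], got {self.efficiency_mean!r}")
        _check_finite_nonneg("efficiency_sd", self.efficiency_sd)
        _check_finite_nonneg("group_noise_cv", self.group_noise_cv)


@dataclass
class TracerTable:
    """Observed tracer counts plus the hidden simulation truth (for tests)."""

    data: pd.DataFrame           # zt_hr, group_id, body_counts, excreta_counts
    true_coeffs: tuple[float, float, float]
    true_efficiency_mean: float


def quadratic(x: np.ndarray, coeffs: tuple[float, float, float]) -> np.ndarray:
    c0, c1, c2 = coeffs
    x = np.asarray(x, dtype=float)
    return c0 + c1 * x + c2 * x**2


def simulate_tracer_assay(config: TracerScenarioConfig) -> TracerTable:
    rng = np.random.default_rng(config.seed)
    rows = []
    cv = config.group_noise_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    for zt in config.zt_times:
        mu = float(quadratic(np.array([zt]), config.intake_coeffs)[0])
        if mu <= 0:
            raise ValueError(f"intake quadratic must be positive at every zt; got {mu} at zt={zt}")
        for g in range(config.n_groups_per_time):
            noise = rng.lognormal(-sigma**2 / 2.0, sigma) if sigma > 0 else 1.0
            intake = mu * noise
            if config.efficiency_sd > 0:
                a = (1e-9 - config.efficiency_mean) / config.efficiency_sd
                b = (1.0 - config.efficiency_mean) / config.efficiency_sd
                eff = float(
                    stats.truncnorm.rvs(
                        a, b, loc=config.efficiency_mean, scale=config.efficiency_sd, random_state=rng
                    )
                )
            else:
                eff = config.efficiency_mean
            body = eff * intake
            rows.append((zt, f"zt{zt:g}_g{g + 1}", body, intake - body))
    data = pd.DataFrame(rows, columns=["zt_hr", "group_id", "body_counts", "excreta_counts"])
    return TracerTable(
        data=data,
        true_coeffs=config.intake_coeffs,
        true_efficiency_mean=config.efficiency_mean,
    )


# ---------------------------------------------------------------------------
# Clock-reporter cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterScenarioConfig:
    """Design of one simulated clock-reporter (nuclear GFP) quantification.

    EC mode emulates per-cell nuclear/cytoplasmic intensities in midgut
    regions R1-R5 with a 24-h cosine nuclear rhythm; EEC mode emulates
    per-gut counts of reporter-positive cells oscillating between
    ``eec_positive_peak`` and ``eec_positive_trough``.  In EEC mode,
    positive cells are placed above the k*SD positivity threshold and
    negative cells below it, so the count is the Poisson truth.
    """

    cell_type: str = "EC"
    n_guts: int = 15
    cells_per_region: int = 10
    nuclear_base: float = 100.0
    nuclear_amp: float = 40.0
    cyto_level: float = 60.0
    phase_by_condition: tuple[tuple[str, float], ...] = (("default", 0.0),)
    noise_cv: float = 0.2
    eec_positive_peak: float = 20.0
    eec_positive_trough: float = 2.0
    eec_cells_per_gut: int = 60
    positivity_k: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in ("EC", "EEC"):
            raise ValueError(f"cell_type must be 'EC' or 'EEC', got {self.cell_type!r}")
        if self.n_guts < 1:
            raise ValueError("n_guts must be >= 1")
        _check_finite_nonneg("nuclear_base", self.nuclear_base, allow_zero=False)
        _check_finite_nonneg("nuclear_amp", self.nuclear_amp)
        _check_finite_nonneg("cyto_level", self.cyto_level)
        _check_finite_nonneg("noise_cv", self.noise_cv)
        if self.cell_type == "EEC" and self.eec_positive_peak < self.eec_positive_trough:
            raise ValueError("eec_positive_peak must be >= eec_positive_trough")

    def acrophase(self, condition: str = "default") -> float:
        for name, phase in self.phase_by_condition:
            if name == condition:
                return phase
        raise KeyError(f"condition {condition!r} not in phase_by_condition")


def _noisy(rng: np.random.Generator, level: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.asarray(level, dtype=float)
    return np.maximum(np.asarray(level) * (1.0 + rng.normal(0.0, cv, size=np.shape(level))), 0.0)


def simulate_reporter_cells(
    config: ReporterScenarioConfig,
    timepoints: list[float],
    condition: str = "default",
) -> pd.DataFrame:
    """Generate a per-cell intensity table (columns: gut_id, region, cell_id,
    timepoint_hr, f_nucleus, f_cytoplasm, cell_type).

    Guts are sampled cross-sectionally: each timepoint gets its own cohort of
    ``n_guts`` dissected guts, as in the real fixed-tissue design.
    """
    if not timepoints:
        raise ValueError("timepoints must be a nonempty list of hours")
    rng = np.random.default_rng(config.seed)
    phase = config.acrophase(condition)
    rows = []
    if config.cell_type == "EC":
        for ti, t in enumerate(timepoints):
            nuc_mean = config.nuclear_base + config.nuclear_amp * math.cos(
                2 * math.pi * (t - phase) / 24.0
            )
            for g in range(config.n_guts):
                gut = f"t{ti}_gut{g + 1:02d}"
                for region in MIDGUT_REGIONS:
                    n = config.cells_per_region
                    f_nuc = _noisy(rng, np.full(n, nuc_mean), config.noise_cv)
                    f_cyt = _noisy(rng, np.full(n, config.cyto_level), config.noise_cv)
                    for c in range(n):
                        rows.append(
                            (gut, region, f"{gut}_{region}_c{c + 1:02d}", float(t),
                             f_nuc[c], f_cyt[c], "EC")
                        )
    else:
        bg_sd = max(config.nuclear_base * config.noise_cv, 1e-6)
        threshold = config.nuclear_base + config.positivity_k * bg_sd
        pos_level = config.nuclear_base + config.nuclear_amp + config.positivity_k * bg_sd
        for ti, t in enumerate(timepoints):
            frac = 0.5 * (1.0 + math.cos(2 * math.pi * (t - phase) / 24.0))
            mean_pos = config.eec_positive_trough + (config.eec_positive_peak - config.eec_positive_trough) * frac
            for g in range(config.n_guts):
                gut = f"t{ti}_gut{g + 1:02d}"
                n_pos = int(rng.poisson(mean_pos))
                n_pos = min(n_pos, config.eec_cells_per_gut)
                n_neg = config.eec_cells_per_gut - n_pos
                # negatives: background intensity truncated below the threshold
                b = (threshold - config.nuclear_base) / bg_sd
                f_neg = stats.truncnorm.rvs(
                    -config.nuclear_base / bg_sd, b, loc=config.nuclear_base, scale=bg_sd,
                    size=n_neg, random_state=rng,
                )
                f_pos = np.maximum(
                    pos_level * (1.0 + rng.normal(0.0, config.noise_cv, size=n_pos)),
                    threshold * (1.0 + 1e-6),
                )
                f_all = np.concatenate([f_pos, f_neg])
                f_cyt = _noisy(rng, np.full(f_all.size, config.cyto_level), config.noise_cv)
                for c in range(f_all.size):
                    region = MIDGUT_REGIONS[c % len(MIDGUT_REGIONS)]
                    rows.append(
                        (gut, region, f"{gut}_c{c + 1:03d}", float(t), f_all[c], f_cyt[c], "EEC")
                    )
    return pd.DataFrame(
        rows,
        columns=["gut_id", "region", "cell_id", "timepoint_hr", "f_nucleus", "f_cytoplasm", "cell_type"],
    )


def reporter_background_stats(config: ReporterScenarioConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Per-gut background statistics matching the EEC generator's truth."""
    bg_sd = max(config.nuclear_base * config.noise_cv, 1e-6)
    guts = table["gut_id"].unique()
    return pd.DataFrame(
        {"gut_id": guts, "background_mean": config.nuclear_base, "background_sd": bg_sd}
    )


# ---------------------------------------------------------------------------
# Named feeding scenarios
# ---------------------------------------------------------------------------

#: The study conditions: each scenario is a named override of the wildtype design.
FEEDING_SCENARIOS: dict[str, dict] = {
    # Robust free-running rhythm (wCS-like): 3 d LD entrainment + 3 d DD.
    "wildtype": {},
    # Arrhythmic core-clock mutant: essentially flat rate (a tiny residual
    # modulation stands in for non-circadian masking, far below detectability).
    "clock_mutant": {"rel_amplitude": 0.02},
    # Constant light after entrainment: phase destabilization + damping.
    "constant_light": {
        "regime_free": "LL",
        "phase_diffusion_sd_hr": 2.5,
        "damping_rate": 0.02,
    },
    # Damped DD oscillation (weakened peripheral clock).
    "damped": {"damping_rate": 0.02},
    # Parameter-recovery variant of "damped": a long free run with a strong
    # starting rhythm and a larger population, so the decay spans the series.
    "damped_recovery": {
        "n_flies": 50,
        "days_entrain": 0,
        "days_free": 6,
        "rel_amplitude": 0.9,
        "damping_rate": 0.02,
    },
    # 8-h feeding from time 0 / 16-h fasting schedule (TRF) during all days.
    "time_restricted": {"fasting_schedule": ((8.0, 24.0),)},
}


def scenario_config(name: str, seed: int = 0, **overrides) -> FeedingScenarioConfig:
    """Build the config for a named feeding scenario (optionally overridden)."""
    if name not in FEEDING_SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(FEEDING_SCENARIOS)}")
    kwargs = dict(FEEDING_SCENARIOS[name])
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return FeedingScenarioConfig(**kwargs)
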