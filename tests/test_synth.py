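"""Generator contracts: Poisson law, masking, determinism, phase placement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from flyrhythm.synth import (
    FeedingScenarioConfig,
    ReporterScenarioConfig,
    TracerScenarioConfig,
    quadratic,
    reporter_background_stats,
    scenario_config,
    simulate_feeding_events,
    simulate_reporter_cells,
    simulate_tracer_assay,
)
from flyrhythm.io_binning import bin_events


def _flat_config(**kw):
    base = dict(
        n_flies=1, days_entrain=0, days_free=3, rel_amplitude=0.0,
        baseline_rate=0.5, fly_effect_sd=0.0, recording_gap_hr=0.0, seed=0,
    )
    base.update(kw)
    return FeedingScenarioConfig(**base)


def test_homogeneous_rate_gives_expected_events_per_bin():
    # 0.5 events/hr, 2-h bins -> 1 event per bin on average
    cfg = _flat_config(days_free=100, seed=3)
    log = simulate_feeding_events(cfg)
    counts = np.histogram(log.events["time_hr"], bins=np.arange(0, 2401, 2))[0]
    assert counts.mean() == pytest.approx(1.0, abs=4 * np.sqrt(1.0 / counts.size))


def test_event_counts_are_poisson_distributed():
    # chi-square GOF against Poisson passes at alpha=0.01 in >= 18/20 runs
    passes = 0
    for seed in range(20):
        cfg = _flat_config(days_free=60, baseline_rate=1.0, seed=seed)
        log = simulate_feeding_events(cfg)
        counts = np.histogram(log.events["time_hr"], bins=np.arange(0, 24 * 60 + 1, 2))[0]
        mu = counts.mean()
        kmax = int(stats.poisson.ppf(0.999, mu)) + 1
        expected = stats.poisson.pmf(np.arange(kmax), mu) * counts.size
        expected = np.append(expected, counts.size - expected.sum())  # tail bucket
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1).astype(float)
        keep = expected > 1.0
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        # dof: categories - 1 - 1 estimated parameter
        p = stats.chi2.sf(chi2, keep.sum() - 2)
        passes += p > 0.01
    assert passes >= 18


def test_fasting_schedule_masks_all_events():
    cfg = _flat_config(fasting_schedule=((8.0, 24.0),), baseline_rate=3.0, seed=1)
    log = simulate_feeding_events(cfg)
    tod = np.mod(log.events["time_hr"].to_numpy(), 24.0)
    assert len(log.events) > 0
    assert not np.any((tod >= 8.0) & (tod < 24.0))


def test_same_seed_same_config_is_bit_identical():
    cfg = scenario_config("wildtype", seed=7)
    a = simulate_feeding_events(cfg)
    b = simulate_feeding_events(cfg)
    pd.testing.assert_frame_equal(a.events, b.events)


def test_times_ordered_and_volumes_positive(wildtype_log):
    ev = wildtype_log.events
    assert (ev["volume_uL"] > 0).all()
    for _, g in ev.groupby("fly_id"):
        assert g["time_hr"].is_monotonic_increasing


def test_recording_gap_has_no_events(wildtype_log):
    tod = np.mod(wildtype_log.events["time_hr"].to_numpy(), 24.0)
    assert not np.any(tod < 0.5)


def test_event_phase_matches_rate_acrophase():
    # circular mean of event times-of-day vs the circular mean of the
    # specified rate waveform, computed by independent numerical integration
    cfg = FeedingScenarioConfig(
        n_flies=50, days_entrain=3, days_free=0, rel_amplitude=0.8,
        acrophase_hr=1.0, fly_effect_sd=0.0, baseline_rate=2.0, seed=5,
    )
    log = simulate_feeding_events(cfg)
    tod = np.mod(log.events["time_hr"].to_numpy(), 24.0)
    theta = 2 * np.pi * tod / 24.0
    sim_phase = np.angle(np.mean(np.exp(1j * theta))) % (2 * np.pi) * 24 / (2 * np.pi)

    def rate(t):
        if t < cfg.recording_gap_hr:
            return 0.0
        return max(0.0, 1 + cfg.rel_amplitude * np.cos(2 * np.pi * (t - 1.0) / 24.0))

    re = quad(lambda t: rate(t) * np.cos(2 * np.pi * t / 24), 0, 24, limit=200)[0]
    im = quad(lambda t: rate(t) * np.sin(2 * np.pi * t / 24), 0, 24, limit=200)[0]
    oracle_phase = (np.arctan2(im, re) % (2 * np.pi)) * 24 / (2 * np.pi)
    diff = (sim_phase - oracle_phase + 12) % 24 - 12
    assert abs(diff) < 0.5


def test_masking_conserves_expected_event_count():
    # Monte Carlo total vs numerical integral of the masked rate, ~1e5 events
    cfg = FeedingScenarioConfig(
        n_flies=200, days_entrain=3, days_free=0, rel_amplitude=0.6,
        baseline_rate=10.0, fly_effect_sd=0.0,
        fasting_schedule=((8.0, 24.0),), seed=11,
    )
    log = simulate_feeding_events(cfg)

    def rate(t):
        tod = t % 24
        if tod < cfg.recording_gap_hr or 8.0 <= tod < 24.0:
            return 0.0
        return cfg.baseline_rate * max(0.0, 1 + 0.6 * np.cos(2 * np.pi * (t - 1.0) / 24.0))

    expected = cfg.n_flies * sum(
        quad(rate, 24 * d, 24 * d + 8, limit=400)[0] for d in range(3)
    )
    assert len(log.events) == pytest.approx(expected, rel=0.02)


@pytest.mark.parametrize(
    "field,value",
    [("baseline_rate", -1.0), ("rel_amplitude", 1.5), ("rel_amplitude", float("nan")),
     ("meal_mean_uL", 0.0), ("period_hr", -24.0)],
)
def test_invalid_config_rejected_naming_field(field, value):
    with pytest.raises(ValueError, match=field.split("_")[0]):
        FeedingScenarioConfig(**{field: value})


# --- tracer generator ---------------------------------------------------

def test_tracer_noiseless_split_and_vertex():
    cfg = TracerScenarioConfig(
        group_noise_cv=0.0, efficiency_sd=0.0, efficiency_mean=0.6,
        intake_coeffs=(100.0, 0.0, 1.0), zt_times=(-4.0, 0.0, 4.0), seed=0,
    )
    tab = simulate_tracer_assay(cfg).data
    row = tab[tab["zt_hr"] == 0.0].iloc[0]
    assert row["body_counts"] == pytest.approx(60.0)
    assert row["excreta_counts"] == pytest.approx(40.0)
    # vertex of the default U-shape is the intake minimum across ZTs
    means = tab.groupby("zt_hr")[["body_counts", "excreta_counts"]].sum().sum(axis=1)
    assert means.idxmin() == 0.0  # vertex at -c1/(2 c2) = 0


def test_tracer_counts_nonnegative_and_u_shape_enforced():
    tab = simulate_tracer_assay(TracerScenarioConfig(seed=2)).data
    assert (tab[["body_counts", "excreta_counts"]] >= 0).all().all()
    with pytest.raises(ValueError, match="c2"):
        TracerScenarioConfig(intake_coeffs=(100.0, 1.0, -2.0))


# --- reporter generator -------------------------------------------------

def test_ec_reporter_flat_when_amplitude_zero():
    cfg = ReporterScenarioConfig(cell_type="EC", nuclear_amp=0.0, noise_cv=0.0, seed=0)
    tab = simulate_reporter_cells(cfg, [0.0, 12.0])
    df = tab.assign(delta=tab["f_nucleus"] - tab["f_cytoplasm"])
    means = df.groupby("timepoint_hr")["delta"].mean()
    assert means.loc[0.0] == pytest.approx(means.loc[12.0])


def test_ec_reporter_cosine_sign():
    cfg = ReporterScenarioConfig(cell_type="EC", seed=1)
    tab = simulate_reporter_cells(cfg, [0.0, 12.0])
    df = tab.assign(delta=tab["f_nucleus"] - tab["f_cytoplasm"])
    means = df.groupby("timepoint_hr")["delta"].mean()
    assert means.loc[0.0] > means.loc[12.0]


def test_eec_positive_count_mean_at_peak():
    # peak=20, 6 guts/timepoint: mean count within ~2 SEs of 20, averaged
    # over independent simulations
    counts = []
    for seed in range(12):
        cfg = ReporterScenarioConfig(
            cell_type="EEC", n_guts=6, seed=seed,
            phase_by_condition=(("default", 12.0),),
        )
        tab = simulate_reporter_cells(cfg, [12.0])
        from flyrhythm.reporter import PositivityRule, count_clk_positive
        bg = reporter_background_stats(cfg, tab)
        c = count_clk_positive(tab, PositivityRule(background=bg))
        counts.append(c["n_positive"].mean())
    se = np.sqrt(20.0 / (6 * len(counts)))
    assert np.mean(counts) == pytest.approx(20.0, abs=3 * se)


def test_reporter_requires_timepoints_and_valid_peak_trough():
    with pytest.raises(ValueError, match="timepoints"):
        simulate_reporter_cells(ReporterScenarioConfig(), [])
    with pytest.raises(ValueError, match="peak"):
        ReporterScenarioConfig(cell_type="EEC", eec_positive_peak=1.0, eec_positive_trough=5.0)


def test_quadratic_helper():
    assert quadratic(np.array([2.0]), (1.0, 2.0, 3.0))[0] == pytest.approx(17.0)
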