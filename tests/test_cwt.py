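"""Wavelet analysis: transform correctness, ridge, strength, damping."""

import numpy as np
import pytest

from flyrhythm.cwt import (
    CWTConfig,
    StrengthCurve,
    compute_cwt,
    damping_summary,
    extract_dominant_ridge,
    strength_curves,
)
from flyrhythm.io_binning import BinnedSeries


def _series(values, bin_width=2.0):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * bin_width + 1.5
    return BinnedSeries(bin_center_hr=t, value=values,
                        regime=np.array(["DD"] * values.size, dtype=object),
                        n_flies=1, bin_width_hr=bin_width)


def _time_domain_cwt(series, config, period):
    """Independent oracle: direct time-domain convolution with the analytic
    Morlet wavelet at one scale (no FFT)."""
    x = series.value - series.value.mean()
    t = series.bin_center_hr
    dt = series.bin_width_hr
    s = period / config.fourier_factor
    w0 = config.omega0
    out = np.empty(t.size, dtype=complex)
    # analytic Morlet in time: pi^-1/4 e^{i w0 eta} e^{-eta^2/2} minus the
    # negative-frequency half; construct from its spectrum on a long grid
    m = 8192
    omega = 2 * np.pi * np.fft.fftfreq(m, d=dt)
    psi_hat = np.where(omega > 0,
                       np.pi**-0.25 * np.sqrt(2 * np.pi * s / dt)
                       * np.exp(-0.5 * (s * omega - w0) ** 2), 0.0)
    psi = np.fft.ifft(psi_hat)  # wavelet centred at index 0, wraps at m
    for i in range(t.size):
        acc = 0.0j
        for j in range(t.size):
            acc += x[j] * np.conj(psi[(j - i) % m])
        out[i] = acc
    return np.abs(out) ** 2


def test_zero_series_zero_power(six_day_series):
    s = _series(np.zeros(72))
    scal = compute_cwt(s)
    assert np.allclose(scal.power, 0.0)
    ridge = extract_dominant_ridge(scal)
    assert not ridge.valid.any()


def test_power_quadratic_in_amplitude(six_day_series):
    a = compute_cwt(six_day_series(amplitude=1.0))
    b = compute_cwt(six_day_series(amplitude=2.0))
    np.testing.assert_allclose(b.power, 4.0 * a.power, rtol=1e-10)


@pytest.mark.parametrize("period", [20.0, 24.0, 28.0])
def test_ridge_recovers_sinusoid_period(six_day_series, period):
    scal = compute_cwt(six_day_series(period_hr=period))
    ridge = extract_dominant_ridge(scal)
    ok = ridge.valid & ~ridge.in_coi
    assert ok.sum() > 10
    med = np.median(ridge.period_hr[ok])
    step = (32.0 / 16.0) ** (1 / 63)  # log-spaced grid ratio
    assert abs(np.log(med / period)) <= np.log(step)


def test_fft_matches_time_domain_oracle(six_day_series):
    series = six_day_series(period_hr=24.0)
    config = CWTConfig()
    scal = compute_cwt(series, config)
    k = int(np.argmin(np.abs(scal.period_hr - 24.0)))
    oracle = _time_domain_cwt(series, config, scal.period_hr[k])
    interior = slice(8, 64)  # away from differing pad behaviour at edges
    np.testing.assert_allclose(scal.power[interior, k], oracle[interior], rtol=1e-6)


def test_band_restriction_excludes_fast_component(six_day_series):
    t = np.arange(72) * 2.0 + 1.5
    v = np.cos(2 * np.pi * t / 24.0) + 0.2 * np.cos(2 * np.pi * t / 12.0)
    scal = compute_cwt(_series(v))
    ridge = extract_dominant_ridge(scal)
    ok = ridge.valid & ~ridge.in_coi
    assert abs(np.median(ridge.period_hr[ok]) - 24.0) < 1.0


def test_time_shift_equivariance():
    # two windows of one long signal, offset by k bins: interior, edge-reliable
    # power columns agree after shifting (approximately — the wavelet's
    # Gaussian tails see slightly different data beyond each window)
    rng = np.random.default_rng(2)
    vlong = rng.normal(size=120)
    k = 4
    a = compute_cwt(_series(vlong[:96]))
    b = compute_cwt(_series(vlong[k:96 + k]))
    rows = np.arange(40, 56)
    mask = ~a.coi_mask[rows + k, :] & ~b.coi_mask[rows, :]
    assert mask.any()
    rel = np.abs(b.power[rows, :][mask] - a.power[rows + k, :][mask]) / np.maximum(
        a.power[rows + k, :][mask], 1e-12
    )
    assert np.median(rel) < 0.01
    assert np.percentile(rel, 90) < 0.05


def test_coi_symmetric(six_day_series):
    scal = compute_cwt(six_day_series())
    np.testing.assert_array_equal(scal.coi_mask, scal.coi_mask[::-1, :])


def test_power_monotone_in_variance(six_day_series):
    weak = compute_cwt(six_day_series(amplitude=0.5))
    strong = compute_cwt(six_day_series(amplitude=1.5))
    assert strong.power.sum() > weak.power.sum()


def test_nan_series_rejected(six_day_series):
    s = six_day_series()
    s.value[3] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        compute_cwt(s)


def test_short_series_rejected():
    with pytest.raises(ValueError, match="short"):
        compute_cwt(_series(np.ones(10)))


# --- strength curves ----------------------------------------------------

def test_single_group_mean_strength_is_one(six_day_series):
    curves = strength_curves({"a": compute_cwt(six_day_series())})
    c = curves["a"]
    assert c.strength[c.valid].mean() == pytest.approx(1.0)


def test_half_amplitude_group_has_quarter_strength(six_day_series):
    curves = strength_curves({
        "full": compute_cwt(six_day_series(amplitude=1.0)),
        "half": compute_cwt(six_day_series(amplitude=0.5)),
    })
    assert curves["full"].strength[curves["full"].valid].mean() == pytest.approx(1.0)
    assert curves["half"].strength[curves["half"].valid].mean() == pytest.approx(0.25)


def test_identical_groups_identical_curves(six_day_series):
    curves = strength_curves({
        "a": compute_cwt(six_day_series()),
        "b": compute_cwt(six_day_series()),
    })
    np.testing.assert_allclose(curves["a"].strength, curves["b"].strength)
    assert curves["a"].strength[curves["a"].valid].mean() == pytest.approx(1.0)


def test_all_invalid_groups_error():
    with pytest.raises(ValueError, match="invalid"):
        strength_curves({"z": compute_cwt(_series(np.zeros(72)))})


# --- damping ------------------------------------------------------------

def _curve(t, strength):
    return StrengthCurve(time_hr=t, strength=strength,
                         valid=np.ones(t.size, dtype=bool), norm_constant=1.0, group="g")


def test_constant_strength_zero_slope():
    t = np.arange(20.0)
    assert damping_summary(_curve(t, np.ones(20))) == pytest.approx(0.0, abs=1e-9)


def test_exponential_decay_recovered_exactly():
    t = np.arange(40.0)
    gamma = 0.013
    slope = damping_summary(_curve(t, np.exp(-gamma * t)))
    assert slope == pytest.approx(-gamma, rel=1e-6)


def test_damping_needs_six_points():
    t = np.arange(5.0)
    with pytest.raises(ValueError, match="6"):
        damping_summary(_curve(t, np.ones(5)))
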