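import numpy as np
import pytest

from flyrhythm.io_binning import BinnedSeries
from flyrhythm.synth import FeedingScenarioConfig, simulate_feeding_events


@pytest.fixture
def wildtype_log():
    """One simulated 3 d LD + 3 d DD experiment with the default design."""
    return simulate_feeding_events(FeedingScenarioConfig(seed=42))


@pytest.fixture
def six_day_series():
    """Factory for clean sinusoidal series on the 6-day, 2-h nominal grid."""

    def make(period_hr=24.0, amplitude=1.0, offset=2.0, phase_hr=0.0, regime="DD"):
        t = np.arange(72) * 2.0 + 1.5
        v = offset + amplitude * np.cos(2 * np.pi * (t - phase_hr) / period_hr)
        return BinnedSeries(
            bin_center_hr=t,
            value=v,
            regime=np.array([regime] * 72, dtype=object),
            n_flies=1,
            bin_width_hr=2.0,
        )

    return make
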