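import numpy as np
import pytest

from baroseq import BeatSeries, SyntheticConfig, generate


@pytest.fixture
def synthetic_pair():
    """Default synthetic subject (sinusoidal drive, mild noise), 2000 beats."""
    sap, pi, truth = generate(SyntheticConfig(n_beats=2000, seed=11))
    return sap, pi, truth


@pytest.fixture
def random_beat_series():
    """Factory for random-walk beat series with optional gaps."""

    def _make(n, seed=0, gap_indices=(), base=120.0, step_sd=1.0, label="SAP",
              units="mmHg"):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.15, 0.19, n))
        t -= t[0]
        values = base + np.cumsum(rng.normal(0, step_sd, n))
        gap = np.zeros(n, dtype=bool)
        gap[list(gap_indices)] = True
        return BeatSeries(t, values, label=label, units=units, gap_after=gap)

    return _make
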