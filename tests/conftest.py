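import numpy as np
import pytest

from gaitseg.signals import TimeSeries
from gaitseg.synthetic import (
    NOISE_PRESETS,
    GaitModelParams,
    ImuNoiseParams,
    generate_trial,
)


def series(values, rate=1.0, t0=0.0, **kw) -> TimeSeries:
    return TimeSeries(values=np.asarray(values, float), rate=rate, t0=t0, **kw)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free reference trial: 1.3 m/s level, 12 strides."""
    return generate_trial(GaitModelParams(seed=7), ImuNoiseParams(), n_strides=12)


@pytest.fixture(scope="session")
def lab_trial():
    """Lab-noise trial at the default condition, 12 strides."""
    return generate_trial(GaitModelParams(seed=11), NOISE_PRESETS["lab"], n_strides=12)
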