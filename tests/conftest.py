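import numpy as np
import pytest

from adamsim import AdamParams, generate_series, make_trend_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def params_kp0():
    """Deterministic model: no perceptual noise."""
    return AdamParams(kp=0.0)


@pytest.fixture
def params_default():
    return AdamParams()


def _zero_noise_series(direction, consistency):
    spec = make_trend_spec(direction, consistency, noise_variance=0.0)
    return spec, generate_series(spec, np.random.default_rng(0))


@pytest.fixture
def zero_noise():
    """Factory for (spec, series) pairs with the noise term at its mean."""
    return _zero_noise_series
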