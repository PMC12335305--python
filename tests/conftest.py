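"""Shared fixtures: seeded RNG and canonical synthetic device specs."""

import numpy as np
import pytest

from mupadkit.synthetic import ResponseParams, SyntheticSpec

BASE_SEED = 20260927


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture
def dopamine_response():
    """Saturation response of the best catalysed device: b=4.26 %/mM over 0.01–10 mM."""
    return ResponseParams(channel="S", intercept=10.0, slope=4.26,
                          linear_range=(0.01, 10.0))


@pytest.fixture
def nadh_hue_response():
    """Hue response crossing the 360→0 wrap, to exercise circular handling."""
    return ResponseParams(channel="H", intercept=350.0, slope=6.0,
                          linear_range=(0.01, 10.0), base_hsv=(0.0, 50.0, 85.0))


@pytest.fixture
def noiseless_spec(dopamine_response):
    return SyntheticSpec(concentrations=(0.5, 2.0, 5.0, 8.0),
                         response=dopamine_response,
                         noise_sd=0.0, vignette_strength=0.0, seed=BASE_SEED)


@pytest.fixture
def noisy_spec(dopamine_response):
    return SyntheticSpec(concentrations=(0.5, 2.0, 5.0, 8.0),
                         response=dopamine_response,
                         noise_sd=3.0, vignette_strength=0.0, seed=BASE_SEED)
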