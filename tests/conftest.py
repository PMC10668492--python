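import numpy as np
import pytest

from dualdelta import phantom


@pytest.fixture(scope="session")
def quiet_pair():
    """Zero-growth, zero-motion, zero-noise pair: baseline == follow-up."""
    spec = phantom.PhantomSpec(seed=1)
    return phantom.generate_pair(spec)


@pytest.fixture(scope="session")
def textured_pair():
    """A realistic moving, growing, noisy pair for downstream stages."""
    spec = phantom.PhantomSpec(
        radii_mm=(6.0, 6.0, 6.0),
        growth_rates_per_day=(0.004, 0.002, 0.001),
        texture_sd_hu=20.0,
        motion_translation_mm=(2.0, 1.0, -1.5),
        motion_rotation_deg=3.0,
        noise_sd_hu=5.0,
        interval_days=90.0,
        seed=3,
    )
    return phantom.generate_pair(spec, label=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
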