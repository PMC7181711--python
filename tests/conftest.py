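import numpy as np
import pytest

from dceus.bolus import FitConfig, lognormal_model
from dceus.synth import CohortSpec, generate_phantom, simulate_bolus_4d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """12^3 phantom shared by map-level tests."""
    return generate_phantom(shape_zyx=(12, 12, 12), heterogeneity_scale=2.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    return CohortSpec(noise_level=0.0, scale_jitter_sigma=0.0,
                      frame_rate_hz=2.0, duration_s=120.0,
                      shape_zyx=(12, 12, 12), seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(small_phantom, noiseless_spec):
    vol = simulate_bolus_4d(small_phantom, noiseless_spec, seed=11)
    return vol, small_phantom, noiseless_spec


def sample_curve(auc=50.0, mu=1.5, sigma=0.4, t0=2.0, rate=2.0, dur=120.0):
    t = np.arange(int(dur * rate)) / rate
    return t, lognormal_model(t, auc, mu, sigma, t0)
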