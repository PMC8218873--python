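import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nss_small():
    """Small benchtop-style recording with ground truth (4 ch, 10 s)."""
    from bcilink.signals import generate_spike_truth, nss_preset, synthesize_broadband

    config = nss_preset(n_channels=4, duration_s=10.0, seed=42)
    truth = generate_spike_truth(config)
    recording = synthesize_broadband(config, truth)
    return config, truth, recording


@pytest.fixture(scope="session")
def bridged_small(nss_small):
    """The small recording run through the zero-impairment wireless chain."""
    from bcilink.link import LinkSpec
    from bcilink.pipeline import wireless_path

    _, _, recording = nss_small
    return wireless_path(recording, spec=LinkSpec(n_channels=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
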