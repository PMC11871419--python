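import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synflux as sf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ctrl():
    return sf.make_preset("CTRL")


@pytest.fixture(scope="session")
def syphy_prot():
    return sf.syphy_protocol()


@pytest.fixture(scope="session")
def tiny_syphy_cfg():
    """Small noise-free sypHy field for identity checks."""
    return sf.default_config(
        "syphy", shape=(64, 64), n_puncta=(1, 1), poisson=False,
        read_noise_sigma=0.0, bleach_tau_frames=None, edge_margin=16,
    )


def constant_stack(value, n_frames=10, shape=(64, 64), frame_rate=1.0):
    return sf.ImageStack(np.full((n_frames, *shape), float(value)),
                         frame_rate_hz=frame_rate)
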