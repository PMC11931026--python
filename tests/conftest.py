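import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_capture():
    """A small rendered two-ring capture shared across I/O and pipeline tests."""
    from plantnerf import scene_sim

    return scene_sim.make_capture(
        seed=3, n_per_ring=6, h=32, w=32, n_quad=48, n_leaves=6, n_heldout=1
    )
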