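import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zonemetrics import PhantomSpec, generate_phantom, make_session_from_truth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_phantom():
    """256² noiseless circular phantom: fast shared fixture."""
    spec = PhantomSpec(
        size=(256, 256), r_lz0=50.0, wave_amplitude=0.0, r_jz_outer=80.0,
        r_dec_outer=110.0, noise_sigma=0.0, seed=7,
        hole_fraction={"LZ": 0.05, "JZ": 0.05, "decidua": 0.05},
    )
    image, truth = generate_phantom(spec)
    session = make_session_from_truth(truth)
    return image, truth, session
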