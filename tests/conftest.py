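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


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def default_stack():
    from ivims.geometry import make_stack

    return make_stack()


@pytest.fixture(scope="session")
def small_sim():
    """One modest spill (5e4 primaries) shared by read-only tests."""
    from ivims.beamline import BeamConfig, FragmentModelConfig, PhantomConfig, simulate_spill
    from ivims.geometry import make_stack

    beam = BeamConfig(n_primaries=50_000, nominal_range=105.2, seed=42)
    sim = simulate_spill(beam, PhantomConfig(), FragmentModelConfig(), make_stack(), seed=42)
    return sim
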