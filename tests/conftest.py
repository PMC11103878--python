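import pytest

from chromadapt import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default design, seed 1."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_study():
    """Low-noise variant used for planted-effect concordance checks."""
    return simulate_study(SimConfig(seed=11, expression_noise_sd=0.05))
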