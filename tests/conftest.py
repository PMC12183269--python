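import pytest
from hypothesis import HealthCheck, settings

from endosym import EffectModel, StudyDesign, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One full-design simulated experiment (360 plants, 150 qPCR samples)."""
    return simulate_dataset(StudyDesign(seed=7), EffectModel(), seed=7)


@pytest.fixture(scope="session")
def plants(default_dataset):
    return default_dataset["plants"]


@pytest.fixture(scope="session")
def plate(default_dataset):
    return default_dataset["qpcr"]
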