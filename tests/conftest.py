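import pytest
from hypothesis import HealthCheck, settings

from ecknn import GeneratorConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic corpus shared by I/O and classifier tests."""
    config = GeneratorConfig(
        seed=11, n_proteins=300, n_signatures=200, n_leaf_classes=25
    )
    dataset, records = generate_dataset(config)
    return dataset, records


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (5,000 proteins, 200 leaf classes)."""
    dataset, records = generate_dataset(GeneratorConfig(seed=7))
    return dataset, records
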