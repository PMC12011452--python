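import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete synthetic dataset (3 species x 4 seasons x 4)."""
    from dietniche import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        seed=7,
        samples_per_group=4,
        n_taxa_per_pool=12,
        depth_meanlog=float(np.log(3000)),
    )
    return generate_dataset(cfg)
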