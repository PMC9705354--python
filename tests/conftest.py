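import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import perturblink as pl

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_symmetric(rng: np.random.Generator, n: int, scale: float = 1.0):
    g = rng.normal(0.0, scale, size=(n, n))
    return (g + g.T) / 2.0


@pytest.fixture(scope="session")
def dataset() -> pl.SyntheticDataset:
    return pl.generate(pl.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def bilayer(dataset) -> pl.BilayerNetwork:
    return pl.build_bilayer(dataset.sl, dataset.sm, dataset.interactions)
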