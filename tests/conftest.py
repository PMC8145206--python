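import dataclasses

import numpy as np
import pytest

from mirbw import Dataset, GeneratorConfig, WavenumberGrid, generate

# A compact test grid: 175 points in the fingerprint-to-amide region, same
# spacing family as the full instrument window, so region intervals and the
# gap derivative behave realistically at a fraction of the cost.
SMALL_GRID = WavenumberGrid(925.66, 1599.66, 175)


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    return SMALL_GRID


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(
        grid=SMALL_GRID,
        n_herds=9,
        cows_per_herd=(8, 14),
        records_per_cow=(3, 6),
        seed=1,
    )


@pytest.fixture(scope="session")
def synthetic(gen_config):
    """One mid-sized multi-herd dataset (~480 records) plus its truth."""
    return generate(gen_config)


@pytest.fixture()
def dataset(synthetic) -> Dataset:
    ds, _ = synthetic
    return ds.copy()


def quiet_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
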