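import numpy as np
import pandas as pd
import pytest

from traitspace import GeneratorCalibration, fit_space, generate_reference


@pytest.fixture(scope="session")
def default_table():
    """Synthetic reference under the default calibration (2,214 entities)."""
    return generate_reference()


@pytest.fixture(scope="session")
def default_space(default_table):
    return fit_space(default_table)


@pytest.fixture(scope="session")
def small_table():
    return generate_reference(GeneratorCalibration(n_entities=300, seed=7))


@pytest.fixture(scope="session")
def small_space(small_table):
    return fit_space(small_table)


def random_trait_table(rng: np.random.Generator, n: int, p: int) -> pd.DataFrame:
    """A random positive trait table with correlated log-scale columns."""
    from traitspace import CANONICAL_TRAITS

    traits = list(CANONICAL_TRAITS[:p])
    latent = rng.standard_normal((n, p)) @ rng.standard_normal((p, p)) * 0.4
    table = pd.DataFrame(10.0 ** latent, columns=traits)
    table.insert(0, "entity_id", [f"e{i}" for i in range(n)])
    return table
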