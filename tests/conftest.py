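import numpy as np
import pytest

from gctract.simdata import GeneratorSpec, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 2 Mb, 200-individual panel at default site density (seeded)."""
    return simulate_panel(region_length=2_000_000, n_individuals=200, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def geom100_spec():
    return GeneratorSpec("geom", phi=100)
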