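import numpy as np
import pytest

from barrelbiome import OtuTable, load_fixture


@pytest.fixture(scope="session")
def fb_16s():
    return load_fixture("fb_16s")


@pytest.fixture(scope="session")
def icvv_16s():
    return load_fixture("icvv_16s")


@pytest.fixture(scope="session")
def fb_its():
    return load_fixture("fb_its")


@pytest.fixture(scope="session")
def icvv_its():
    return load_fixture("icvv_its")


@pytest.fixture
def small_table():
    """A tiny hand-sized table with zeros, for unit arithmetic."""
    return OtuTable(
        taxa=("alpha", "beta", "gamma"),
        samples=("s1", "s2"),
        counts=np.array([[6, 0], [2, 5], [4, 5]]),
    )


def random_composition(rng, n_taxa=None, n_samples=None):
    """Strictly positive random composition values for oracle checks."""
    n_taxa = n_taxa or rng.integers(4, 9)
    n_samples = n_samples or rng.integers(2, 6)
    values = rng.gamma(2.0, 50.0, size=(n_taxa, n_samples)) + 0.5
    taxa = tuple(f"t{i:02d}" for i in range(n_taxa))
    samples = tuple(f"s{j}" for j in range(n_samples))
    return taxa, samples, values
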