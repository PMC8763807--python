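import numpy as np
import pytest

from zcount.synthdata import SyntheticSpec, generate_stack


def sparse_spec(**overrides) -> SyntheticSpec:
    """Oracle-exact regime: separation guarantees non-touching cells."""
    base = dict(
        n_cells=12, shape=(8, 192, 192), radius_range=(4.0, 6.0),
        z_extent_range=(3, 5), min_separation=2 * 6.0 + 4,
        noise_sigma=10.0, seed=7,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def sparse_phantom():
    """A small phantom with well-separated cells, shared across tests."""
    return generate_stack(sparse_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
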