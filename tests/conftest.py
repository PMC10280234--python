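import numpy as np
import pytest

from carn.fixtures import FixtureSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """16 small synthetic tissue patches with truth table, on disk."""
    out = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(size=64, n_images=16, seed=7)
    rows = generate_dataset(spec, out)
    return out, rows
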