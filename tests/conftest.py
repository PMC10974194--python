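import numpy as np
import pytest

import wheattherm as wt


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture(scope="session")
def fixture_tables():
    """Packaged published index and yield tables, keyed by species."""
    return wt.paper_fixture_tables()


@pytest.fixture
def two_class_frame(rng):
    """A standard well-separated synthetic frame with ground truth."""
    return wt.generate_frame(25.0, 20.0, 0.5, 0.5, 0.7, rng=rng)
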