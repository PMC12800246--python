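import numpy as np
import pytest

from morphodisp import make_outline_scheme
from morphodisp.synthetic import default_truth, simulate_dataset


@pytest.fixture(scope="session")
def scheme():
    """Small fish-outline scheme: 11 fixed + 25 semi-landmarks."""
    return make_outline_scheme(11, 25)


@pytest.fixture(scope="session")
def study_bundle(scheme):
    """Default study-shaped synthetic dataset: 36 species, 8 groups."""
    template, sliders = scheme
    truth, census = default_truth(template=template, seed=7)
    configs, meta = simulate_dataset(truth, census, seed=7)
    for c in configs:
        c.semilandmark_flags = template.semilandmark_flags.copy()
    return configs, sliders, meta, truth, census


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_configuration(rng, k=8, scale=1.0):
    """A non-degenerate random k-point configuration."""
    pts = rng.normal(0, 1, size=(k, 2)) * scale
    return pts
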