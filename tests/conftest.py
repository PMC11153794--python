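import numpy as np
import pytest

from cytotome.config import RunConfig
from cytotome.phantom import make_three_region_phantom
from cytotome.pipeline import build_coordinates


@pytest.fixture(scope="session")
def three_region():
    """One graded three-region slab phantom shared across the session."""
    vol, truth = make_three_region_phantom(seed=11, mode="graded")
    return vol, truth


@pytest.fixture(scope="session")
def three_region_coords(three_region):
    """Solved coordinate system for the shared three-region phantom."""
    _, truth = three_region
    cfg = RunConfig(knn_k=50, n_clusters=3, rng_seed=11)
    return build_coordinates(truth.mask, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
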