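import numpy as np
import pytest

from allodyn import generate_toy_ensemble
from allodyn.ensemble_io import ensemble_from_calpha
from allodyn.synthetic_fixtures import ToyReceptorSpec, delta_anchor_ids


@pytest.fixture(scope="session")
def toy():
    """Default-parameter toy ensemble with ground truth (seed 0)."""
    ensemble, truth = generate_toy_ensemble(ToyReceptorSpec(seed=0))
    return ensemble, truth


@pytest.fixture(scope="session")
def toy_anchors(toy):
    ensemble, truth = toy
    return delta_anchor_ids(ensemble, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_ensemble(rng, n_frames, n_res, scale=5.0):
    """A geometry-free random ensemble for numerical cross-checks."""
    coords = rng.normal(size=(n_frames, n_res, 3)) * scale
    return ensemble_from_calpha(coords)


@pytest.fixture()
def make_random_ensemble(rng):
    def _make(n_frames=10, n_res=6, scale=5.0):
        return random_ensemble(rng, n_frames, n_res, scale)

    return _make
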