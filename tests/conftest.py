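import numpy as np
import pytest

import repgeom as rg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stimuli():
    """4 categories x 3 exemplars = 12 conditions."""
    return rg.make_stimulus_set(4, 3)


@pytest.fixture
def small_truth():
    return rg.GroundTruth(
        n_subjects=4,
        n_categories=4,
        n_exemplars=3,
        n_units_per_neighborhood=80,
        noise_sd=0.5,
        mixture_weights={"nbhd00": (1.0, 0.0, 0.0)},
        seed=11,
    )


@pytest.fixture
def small_models(small_stimuli, small_truth):
    return rg.simulate_model_rdms(small_stimuli, small_truth)


def random_rdm(rng, n, labels=None):
    """Helper: random valid RDM from points in 4-D."""
    pts = rng.normal(size=(n, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    labels = labels or tuple(f"c{i}" for i in range(n))
    return rg.RDM(d, labels)
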