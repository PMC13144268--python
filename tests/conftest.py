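import numpy as np
import pytest

from fastdat import phantom, preprocess


@pytest.fixture(scope="session")
def small_spec():
    """Reduced phantom grid for fast unit tests (geometry scales with grid)."""
    return phantom.PhantomSpec(grid_xy=(64, 64), n_slices=9, counts_per_cycle=50_000.0)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return phantom.make_activity_volume(small_spec, left=4, right=3, seed=5)


@pytest.fixture(scope="session")
def small_pair(small_case):
    return phantom.simulate_acquisition_pair(small_case, seed=17)


@pytest.fixture(scope="session")
def default_case():
    """Full-size (128 x 128) case, needed wherever the 64 x 64 crop applies."""
    return phantom.make_activity_volume(phantom.PhantomSpec(), left=4, right=2, seed=9)


@pytest.fixture(scope="session")
def default_samples(default_case):
    pair = phantom.simulate_acquisition_pair(default_case, seed=23)
    selection = preprocess.select_slices(
        preprocess.normalize_case(pair.long_stack), case_id=default_case.case_id
    )
    return preprocess.build_samples(pair, selection)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
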