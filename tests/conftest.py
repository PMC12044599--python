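import numpy as np
import pytest

from denoisebench.preproc import PreprocConfig
from denoisebench.synthcohort import (
    CohortParams,
    make_phantom,
    simulate_motion,
    simulate_noise,
    simulate_subject,
)
from denoisebench.types import AcquisitionGrid
from denoisebench.workbench import prepare_subject

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def grid():
    return AcquisitionGrid(dims=(16, 16, 16), tr=2.5, n_volumes=200)


@pytest.fixture(scope="session")
def small_grid():
    return AcquisitionGrid(dims=(12, 12, 12), tr=2.5, n_volumes=100)


@pytest.fixture(scope="session")
def phantom(grid):
    return make_phantom(grid, n_rois=14, seed=0)


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return make_phantom(small_grid, n_rois=7, seed=0)


@pytest.fixture(scope="session")
def cohort_params(grid):
    return CohortParams(grid=grid)


@pytest.fixture(scope="session")
def subject(grid, phantom, cohort_params):
    """One fully simulated + minimally preprocessed high-motion subject."""
    tissue, parc = phantom
    bold, motion = simulate_subject(tissue, parc, grid, "high", 42, cohort_params)
    return prepare_subject("sub-001", bold, tissue, motion, PreprocConfig(), seed=42)


@pytest.fixture(scope="session")
def raw_noise_subject(grid, phantom):
    tissue, _ = phantom
    motion = simulate_motion(grid.n_volumes, "high", seed=3)
    vol = simulate_noise(grid, tissue, motion, seed=4)
    return vol, motion, tissue


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
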