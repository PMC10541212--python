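import numpy as np
import pytest

from rsibreast.phantom import PhantomConfig, generate_cohort
from rsibreast.pipeline import RunConfig, run_cohort_pipeline
from rsibreast.rsi_fit import RsiFixedAdcs
from rsibreast.volumes_io import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return ImageGrid(shape=(8, 6, 4), spacing=(2.5, 2.5, 5.0))


@pytest.fixture
def dwi_grid():
    """Acquisition-like anisotropic grid at reduced matrix size."""
    return ImageGrid(shape=(32, 32, 8), spacing=(2.5, 2.5, 5.0))


@pytest.fixture
def example_adcs():
    return RsiFixedAdcs.example()


@pytest.fixture(scope="session")
def small_phantom_template():
    return PhantomConfig(grid=ImageGrid((32, 32, 8), (2.5, 2.5, 5.0)))


@pytest.fixture(scope="session")
def noiseless_small_cohort(small_phantom_template):
    """Six-patient noiseless cohort on a small grid, shared across tests."""
    return generate_cohort(
        n_patients=6, pcr_fraction=0.5, template=small_phantom_template, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_small_dataset(noiseless_small_cohort):
    return run_cohort_pipeline(noiseless_small_cohort, RunConfig())
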