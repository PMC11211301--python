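import numpy as np
import pytest

from spectrc.experiments import SweepConfig, run_sweep
from spectrc.phantom import PhantomConfig, VoxelGrid


@pytest.fixture(scope="session")
def spect_config():
    return PhantomConfig.nema_spect()


@pytest.fixture(scope="session")
def pet_config():
    return PhantomConfig.nema_pet()


@pytest.fixture(scope="session")
def small_grid():
    """Small centered grid for operator-level tests."""
    return VoxelGrid.centered((32, 32, 8), 9.6)


@pytest.fixture(scope="session")
def desk_sweep():
    """The 24-permutation desk-scale sweep of the NEMA SPECT phantom.

    Runs the full pipeline once per session; several structural checks
    (spread ordering, convergence plateau, extreme positions) share it.
    """
    return run_sweep(SweepConfig(master_seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
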