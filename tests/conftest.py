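import warnings

import numpy as np
import pytest

from spiralcine.mri_sim import gridded_series, make_training_example
from spiralcine.presets import resolve_preset
from spiralcine.synthetic_data import PhantomSpec, make_phantom_cine
from spiralcine.trajectory import ImagingGrid, SpiralParams, build_trajectory


@pytest.fixture(scope="session")
def grid64():
    return ImagingGrid(64, 400.0)


@pytest.fixture(scope="session")
def grid32():
    return ImagingGrid(32, 400.0)


@pytest.fixture(scope="session")
def optimized_params():
    return resolve_preset("optimized")


@pytest.fixture(scope="session")
def uniform_params():
    return resolve_preset("uniform")


def nyquist_params(n_interleaves: int) -> SpiralParams:
    """Uniform-density spiral at exactly the frame Nyquist rate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SpiralParams(
            r_inner=1.0,
            a_inner=float(n_interleaves),
            r_outer=1.0,
            density_ratio=1.0,
            transition="linear",
            ordering="linear",
            tr_ms=3.67,
            n_interleaves=n_interleaves,
        )


@pytest.fixture(scope="session")
def traj_optimized_64(grid64, optimized_params):
    return build_trajectory(optimized_params, grid64, 1, samples_per_interleave=256)


@pytest.fixture(scope="session")
def cine64():
    return make_phantom_cine(PhantomSpec(grid=ImagingGrid(64, 400.0), n_frames=16, seed=3))


@pytest.fixture(scope="session")
def cine32():
    return make_phantom_cine(
        PhantomSpec(grid=ImagingGrid(32, 400.0), n_frames=12, n_coils=2, seed=7)
    )


@pytest.fixture(scope="session")
def small_training_set(cine64, traj_optimized_64):
    gridded = gridded_series(cine64, traj_optimized_64)
    return [
        make_training_example(cine64, traj_optimized_64, t, gridded=gridded)
        for t in range(5, cine64.n_frames + 1)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
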