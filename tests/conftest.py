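import numpy as np
import pytest

from cdcyto import benchmarks, simulate


@pytest.fixture(scope="session")
def small_video():
    """10-cell, 3-lane synthetic video with default imaging noise (seeded)."""
    geom = benchmarks.benchmark_geometry(3)
    imaging = simulate.ImagingModel()
    frames, truth, _ = simulate.simulate_video(
        n_cells=10, geom=geom, imaging=imaging, seed=7
    )
    return frames, truth, geom, imaging


@pytest.fixture(scope="session")
def noiseless_video():
    """4-cell, 2-lane video rendered without sensor noise (blur only)."""
    geom = benchmarks.benchmark_geometry(2)
    imaging = simulate.ImagingModel(noise_sigma=0.0)
    frames, truth, _ = simulate.simulate_video(
        n_cells=4, geom=geom, imaging=imaging, seed=3
    )
    return frames, truth, geom, imaging


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
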