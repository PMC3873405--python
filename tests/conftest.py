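import numpy as np
import pytest

from saltatrack import AcquisitionMeta, make_benchmark_dataset


@pytest.fixture(scope="session")
def meta():
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def small_meta():
    return AcquisitionMeta(image_shape=(128, 128), n_frames=12)


@pytest.fixture(scope="session")
def benchmark_300(meta):
    """Labelled 300-trajectory benchmark at the default mixture, no rendering."""
    _, truth = make_benchmark_dataset(n_trajectories=300, meta=meta, seed=11, render=False)
    return truth


@pytest.fixture(scope="session")
def rendered_benchmark(meta):
    """A rendered high-SNR movie with moderate spot density plus ground truth."""
    stack, truth = make_benchmark_dataset(n_trajectories=20, meta=meta, seed=5,
                                          photon_scale=400.0, background=20.0)
    return stack, truth
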