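import numpy as np
import pytest

from taskmodules import MotionDataset, PerformanceSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """Random 3-joint, 5-frame, 8-trial dataset with named joints."""
    angles = rng.standard_normal((3, 5, 8)) + np.array([10.0, -5.0, 0.0])[:, None, None]
    return MotionDataset(
        angles=angles, joint_labels=["ankle", "knee", "hip"], sample_rate=100.0
    )


@pytest.fixture
def small_perf(rng, small_dataset):
    d = rng.standard_normal(small_dataset.n_trials) * 3.0 + 40.0
    return PerformanceSeries(
        d_raw=d,
        target=np.full(small_dataset.n_trials, 50.0),
        perturbation=np.zeros(small_dataset.n_trials),
        trial_index=np.arange(small_dataset.n_trials),
    )
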