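import numpy as np
import pytest

from spikepatterns import SpikeDataset, Trial


@pytest.fixture
def tiny_dataset() -> SpikeDataset:
    """Two units, two stimuli, two trials each, TD=100 ms."""
    trials = [
        Trial(0, "a", [np.array([5.0, 20.0]), np.array([50.0])]),
        Trial(1, "a", [np.array([6.0]), np.array([55.0, 60.0])]),
        Trial(2, "b", [np.array([80.0]), np.array([])]),
        Trial(3, "b", [np.array([81.0, 90.0]), np.array([10.0])]),
    ]
    return SpikeDataset(
        units=[0, 1], trials=trials, stimulus_set=["a", "b"], trial_duration_ms=100.0
    )


@pytest.fixture
def random_dataset() -> SpikeDataset:
    """4 units, 3 stimuli, 4 trials each, Poisson-ish spikes, TD=1200 ms."""
    rng = np.random.default_rng(42)
    trials = []
    tid = 0
    for j in range(3):
        for _ in range(4):
            spikes = [
                np.sort(rng.uniform(0, 1200, size=rng.poisson(20)))
                for _ in range(4)
            ]
            trials.append(Trial(tid, j, spikes))
            tid += 1
    return SpikeDataset(
        units=list(range(4)), trials=trials, stimulus_set=[0, 1, 2],
        trial_duration_ms=1200.0,
    )
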