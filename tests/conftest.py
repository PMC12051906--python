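import numpy as np
import pytest

from msalign import DomainDataset, Trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    rng,
    n_subjects=2,
    n_trials=6,
    n_channels=3,
    n_samples=32,
    labels=None,
    rate=128.0,
    domain_id="dom",
):
    """Small random dataset with sequential start times per subject."""
    trials = []
    for s in range(n_subjects):
        for i in range(n_trials):
            lab = labels[i] if labels is not None else int(i % 2)
            sig = rng.standard_normal((n_channels, n_samples)).astype(np.float32)
            trials.append(Trial(sig, lab, f"s{s}", domain_id, float(i)))
    return DomainDataset(trials, n_channels, rate, "synthetic", "test", domain_id)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
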