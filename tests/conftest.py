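import numpy as np
import pytest

from ersknn import SyntheticSpec, TrialSet, generate


@pytest.fixture(scope="session")
def two_class_set():
    """Default 2-class synthetic set (8 ch, 100 trials, 250 Hz, ratio 4)."""
    tset, truth = generate(SyntheticSpec(seed=42))
    return tset, truth


@pytest.fixture()
def tiny_tset():
    """Small deterministic TrialSet for container/IO tests."""
    rng = np.random.default_rng(0)
    return TrialSet(
        data=rng.standard_normal((20, 8, 125)),
        labels=np.tile([0, 1], 10),
        fs=250.0,
        class_names=["left", "right"],
    )
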