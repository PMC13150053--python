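import numpy as np
import pandas as pd
import pytest

from lrpfrac.preprocess import EpochSet


def make_epochs(
    data: np.ndarray,
    channel_labels=("C3", "C4"),
    fs: float = 500.0,
    lock: str = "stimulus",
    window_ms=(-200.0, 600.0),
    baseline_ms=(-200.0, 0.0),
    hands=None,
    correct=None,
) -> EpochSet:
    """Assemble an EpochSet around a raw (trials, channels, samples) array."""
    n = data.shape[0]
    if hands is None:
        hands = ["left" if i % 2 == 0 else "right" for i in range(n)]
    if correct is None:
        correct = [True] * n
    meta = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "hand": hands,
            "compatibility": ["compatible"] * n,
            "correct": correct,
            "rt_ms": np.full(n, 350.0),
        }
    )
    return EpochSet(
        lock=lock,
        window_ms=tuple(window_ms),
        baseline_ms=tuple(baseline_ms),
        data=np.asarray(data, dtype=float),
        channel_labels=list(channel_labels),
        sampling_rate=fs,
        trial_meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
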