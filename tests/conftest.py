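import numpy as np
import pytest

from gaitfuse import (MotionMode, default_profiles, generate_dataset,
                      segment_dataset, split)
from gaitfuse.cnn import DualStreamCNN


@pytest.fixture(scope="session")
def small_windows():
    """Two pseudo-subjects, all four modes, two 8-s repetitions each:
    a small but learnable window set shared across test modules."""
    bundles = generate_dataset(default_profiles(2), list(MotionMode),
                               reps_per_mode=2, duration=8.0, seed=7)
    ws = segment_dataset(bundles)
    return split(ws, seed=7)


@pytest.fixture(scope="session")
def trained_dual(small_windows):
    """A moderately trained dual-stream extractor for feature-level tests."""
    tr = small_windows.split_subset("train")
    va = small_windows.split_subset("val")
    model = DualStreamCNN(epochs=30, random_state=3)
    model.fit(tr.as_matrix(), tr.labels,
              validation_data=(va.as_matrix(), va.labels))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
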