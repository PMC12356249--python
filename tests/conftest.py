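import numpy as np
import pandas as pd
import pytest

from sstclassify import features as feat
from sstclassify import preprocess, synthetic
from sstclassify.session import seconds_to_frames


def make_trial(dff, rate=5.0, trial_type="stimulus", onset_frame=100):
    """Fabricate a TrialWindow directly from a ΔF/F vector.

    ``dff`` must span the full −3 s … +5 s window at ``rate``.
    """
    dff = np.asarray(dff, dtype=float)
    expected = seconds_to_frames(3, rate) + seconds_to_frames(5, rate)
    assert dff.shape == (expected,), (dff.shape, expected)
    return preprocess.TrialWindow(
        trial_type=trial_type, onset_frame=onset_frame, dff=dff,
        baseline_f0=1.0, frame_rate_hz=rate,
    )


def trial_with_peak(peak, rate=5.0, trial_type="stimulus"):
    """Trial whose response-window (0-2 s) max ΔF/F equals ``peak``."""
    n = seconds_to_frames(3, rate) + seconds_to_frames(5, rate)
    dff = np.zeros(n)
    dff[seconds_to_frames(3, rate) + 2] = peak
    return make_trial(dff, rate=rate, trial_type=trial_type)


@pytest.fixture(scope="session")
def two_class_features():
    """Feature matrix + genetic labels for the labeled two-class fixture."""
    exp, truth = synthetic.make_fixture("two-class-labeled", seed=2)
    X, grid = feat.build_feature_matrix(exp)
    y = pd.Series(
        [exp.registry.true_label(c) for c in X.index], index=X.index
    )
    return X, y


@pytest.fixture(scope="session")
def smoke_experiment():
    return synthetic.make_fixture("two-cell-smoke", seed=1)
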