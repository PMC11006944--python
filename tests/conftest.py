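import hypothesis
import numpy as np
import pytest

import ctree_rt as crt

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def generating_model():
    return crt.goalkeeper_generating_tree()


@pytest.fixture(scope="session")
def long_kicks(generating_model):
    """A 20,000-symbol kick sequence shared by calibration tests."""
    return crt.generate_kicks(generating_model, 20_000, seed=1234)


@pytest.fixture()
def worked_session():
    """The nine-trial worked example: kicks 0 2 1 0 1 1 0 2 1.

    Predictions are all-correct except trials 2 and 5 (1-based); response
    times are the trial numbers, so T_n is recognisable in assertions.
    """
    kicks = np.array([0, 2, 1, 0, 1, 1, 0, 2, 1])
    predictions = kicks.copy()
    predictions[1] = 1  # trial 2 wrong (X_2 = 2)
    predictions[4] = 2  # trial 5 wrong (X_5 = 1)
    rts = np.arange(1.0, 10.0)
    return crt.SessionData(kicks, predictions, rts, "worked")
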