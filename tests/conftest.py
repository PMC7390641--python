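import numpy as np
import pytest

from tectodist import EyeGeometry, StimulusKinematics, SyntheticTruth, simulate_trial


@pytest.fixture
def kin() -> StimulusKinematics:
    return StimulusKinematics()


@pytest.fixture
def geo() -> EyeGeometry:
    return EyeGeometry()


@pytest.fixture
def clean_trial(kin, geo):
    """Zero-noise, zero-latency trial at dd_true = 4 mm with its truth."""
    truth = SyntheticTruth(dd_true=4.0, noise_sd=0.0)
    trace, events = simulate_trial(truth, kin, geo, seed=0)
    return trace, events, truth
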