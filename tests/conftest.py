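import numpy as np
import pytest
from hypothesis import settings

from centraldrive.simulate import ParticipantParams
from centraldrive.traces import TorqueTrace

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def neurotypical_params() -> ParticipantParams:
    return ParticipantParams(
        id="P0",
        group="neurotypical",
        limb="dominant",
        mfga=60.0,
        true_cd_max=1.0,
        efficacy_k=1.0,
        noise_sd=0.2,
    )


@pytest.fixture
def paretic_params() -> ParticipantParams:
    return ParticipantParams(
        id="S0",
        group="post-stroke",
        limb="paretic",
        mfga=40.0,
        true_cd_max=0.7,
        efficacy_k=0.75,
        noise_sd=0.35,
    )


def make_trace(samples, trigger=None, fs=1000.0) -> TorqueTrace:
    samples = np.asarray(samples, dtype=float)
    if trigger is None:
        trigger = np.zeros(samples.size, dtype=int)
    return TorqueTrace(samples=samples, trigger=np.asarray(trigger), sampling_rate=fs)


@pytest.fixture
def plateau_with_burst():
    """6-s constant 30 ft-lbs trace with an excursion to 45 after the burst."""
    n = 6000
    samples = np.full(n, 30.0)
    samples[3100:3250] = 45.0
    trigger = np.zeros(n, dtype=int)
    trigger[3000:3150] = 1
    return TorqueTrace(samples=samples, trigger=trigger, sampling_rate=1000.0)
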