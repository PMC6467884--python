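import math

import pytest
from hypothesis import settings

from triadbci.agents import ReceiverModel, SenderModel, TrustState
from triadbci.decoder import DecoderConfig
from triadbci.game import (
    ChannelModel,
    EEGParams,
    make_session_plan,
    run_session,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return DecoderConfig()


@pytest.fixture(scope="session")
def noise_free_session():
    """One session with perfect EEG and a noiseless channel (shared, expensive)."""
    plan = make_session_plan(11)
    return run_session(
        plan,
        senders=(SenderModel(1.0), SenderModel(1.0)),
        receiver=ReceiverModel(),
        channel=ChannelModel(perception_noise=0.0),
        seed=11,
        eeg=EEGParams(snr=math.inf),
    )


@pytest.fixture(scope="session")
def trusting_ideal_session():
    """Noise-free session whose Receiver already fully trusts the good Sender."""
    plan = make_session_plan(5)
    good = plan.bad_sender ^ 1
    agreements = [0, 0]
    agreements[good] = 1000
    receiver = ReceiverModel(
        trust=TrustState(agreements=tuple(agreements), disagreements=(0, 0)),
        explore_start=0.0,
    )
    return run_session(
        plan,
        senders=(SenderModel(1.0), SenderModel(1.0)),
        receiver=receiver,
        channel=ChannelModel(perception_noise=0.0),
        seed=5,
        eeg=EEGParams(snr=math.inf),
    )


@pytest.fixture(scope="session")
def default_session():
    """One session at the default (noisy) operating point."""
    plan = make_session_plan(3)
    return run_session(plan, receiver=ReceiverModel(), seed=3)
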