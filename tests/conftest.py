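import numpy as np
import pytest

from trustlearn.behavior import ParticipantParams, ResponseRecord, responses_to_frame
from trustlearn.ideal import BeliefGrid, state_posterior
from trustlearn.task import (
    BLUE,
    ExperimentDesign,
    generate_block,
    trials_to_frame,
)


@pytest.fixture(scope="session")
def full_design():
    return ExperimentDesign.full_feedback()


@pytest.fixture(scope="session")
def noisy_design():
    return ExperimentDesign.noisy_feedback()


@pytest.fixture(scope="session")
def neutral_params():
    return ParticipantParams.ideal()


def known_responder_confidence(source, X, state_prior=0.5):
    """Confidence of a responder who knows the source parameters exactly."""
    belief = BeliefGrid.point_mass(source.b, source.g)
    return state_posterior(belief, X, source.n_experts, state_prior)


def known_responder_block(source, design, rng, block_index=0, participant_id="k0"):
    """Trials plus noise-free known-parameter responses for one block."""
    trials = generate_block(
        source, design, rng, participant_id=participant_id, block_index=block_index
    )
    responses = [
        ResponseRecord(
            participant_id=t.participant_id,
            block_index=t.block_index,
            trial_index=t.trial_index,
            confidence=known_responder_confidence(source, t.signal_X, design.state_prior),
            revised_confidence=None,
            binarized_choice=BLUE,
        )
        for t in trials
    ]
    return trials, responses


def to_frames(trials, responses):
    return trials_to_frame(trials), responses_to_frame(responses)


def accuracy_of(trials, confidences):
    """Mean binarized accuracy (0.5 credit at an exact tie)."""
    conf = np.asarray(confidences, dtype=float)
    blue = np.array([t.state == BLUE for t in trials])
    return float(
        np.mean(np.where(conf == 0.5, 0.5, ((conf > 0.5) == blue).astype(float)))
    )
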