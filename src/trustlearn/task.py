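"""Generative model of the news-source trust task.

A latent binary state (*blue* vs *green*, "which policy is better") is drawn
each trial with equal probability.  A news source — a panel of ``n_experts``
experts — emits a signal ``X``: the number of experts endorsing blue, drawn
from a binomial whose per-expert success probability depends on the state and
on the source's reliability pair ``(b, g)``:

    X ~ Binomial(n, b)      if the state is blue
    X ~ Binomial(n, 1 - g)  if the state is green

Feedback after the response is either the revealed state (*full* feedback) or
a second, noisy expert panel — the "Independent Council" — whose per-expert
reliability ``b_Y`` is known to the agent (*noisy* feedback).

Each source is experienced in one block of 28 learning trials followed by 6
feedback-free probe trials that present every possible signal count once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

BLUE = "blue"
GREEN = "green"
STATES = (BLUE, GREEN)

FULL = "full"
NOISY = "noisy"

LEARNING = "learning"
PROBE = "probe"


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SourceSpec:
    """A news source's reliability pair and panel size.

    ``b`` is the per-expert probability of a blue endorsement when the state
    is blue; ``g`` the per-expert probability of a green endorsement when the
    state is green.  These two parameters are the object of the higher-level
    inference problem.
    """

    label: str
    b: float
    g: float
    n_experts: int = 5

    def __post_init__(self) -> None:
        _check_prob("b", self.b)
        _check_prob("g", self.g)
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")

    def expert_prob(self, state: str) -> float:
        """Per-expert probability of a *blue* endorsement given the state."""
        if state == BLUE:
            return self.b
        if state == GREEN:
            return 1.0 - self.g
        raise ValueError(f"unknown state {state!r}")


#: The four canonical source archetypes used in the study design.
HELPFUL = SourceSpec("helpful", 0.75, 0.75)
RANDOM = SourceSpec("random", 0.5, 0.5)
OPPOSITE = SourceSpec("opposite", 0.25, 0.25)
BLUE_BIASED = SourceSpec("blue_biased", 0.9, 0.5)

CANONICAL_SOURCES = (HELPFUL, RANDOM, OPPOSITE, BLUE_BIASED)
SOURCES_BY_LABEL = {s.label: s for s in CANONICAL_SOURCES}


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback channel: full state revelation or a noisy council panel."""

    mode: str = FULL
    b_Y: float = 0.75
    n_council: int = 5

    def __post_init__(self) -> None:
        if self.mode not in (FULL, NOISY):
            raise ValueError(f"mode must be 'full' or 'noisy', got {self.mode!r}")
        _check_prob("b_Y", self.b_Y)
        if self.n_council < 1:
            raise ValueError("n_council must be >= 1")

    def council_prob(self, state: str) -> float:
        """Per-expert probability of a blue council endorsement given the state."""
        return self.b_Y if state == BLUE else 1.0 - self.b_Y


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.

    ``feedback_Y`` is the revealed state (full mode), a council count in
    ``0..n_council`` (noisy mode), or ``None`` on probe trials.  Probe trials
    carry a sampled latent state for bookkeeping only; it is never shown to
    the agent and never used to score probes.
    """

    participant_id: str
    block_index: int
    trial_index: int
    source_label: str
    state: str
    signal_X: int
    feedback_Y: object  # str (full), int (noisy) or None (probe)
    phase: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"invalid state {self.state!r}")
        if self.phase not in (LEARNING, PROBE):
            raise ValueError(f"invalid phase {self.phase!r}")
        if self.phase == PROBE and self.feedback_Y is not None:
            raise ValueError("probe trials carry no feedback")


@dataclass(frozen=True)
class ExperimentDesign:
    """Complete design for one experiment condition."""

    condition: str = "full_feedback"
    sources: Sequence[SourceSpec] = CANONICAL_SOURCES
    n_learning_trials: int = 28
    probe_signals: Sequence[int] | None = None  # None -> 0..n_experts
    state_prior: float = 0.5
    feedback: FeedbackConfig | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("full_feedback", "noisy_feedback"):
            raise ValueError(f"unknown condition {self.condition!r}")
        _check_prob("state_prior", self.state_prior)
        if self.feedback is None:
            mode = FULL if self.condition == "full_feedback" else NOISY
            object.__setattr__(self, "feedback", FeedbackConfig(mode=mode))
        expected = FULL if self.condition == "full_feedback" else NOISY
        if self.feedback.mode != expected:
            raise ValueError(
                f"feedback mode {self.feedback.mode!r} inconsistent with "
                f"condition {self.condition!r}"
            )

    @property
    def n_experts(self) -> int:
        return self.sources[0].n_experts

    def probe_counts(self) -> list[int]:
        if self.probe_signals is None:
            return list(range(self.n_experts + 1))
        return list(self.probe_signals)

    @classmethod
    def full_feedback(cls, **kwargs) -> "ExperimentDesign":
        return cls(condition="full_feedback", **kwargs)

    @classmethod
    def noisy_feedback(cls, **kwargs) -> "ExperimentDesign":
        return cls(condition="noisy_feedback", **kwargs)


def signal_pmf(source: SourceSpec, state: str) -> np.ndarray:
    """Probability vector over signal counts ``0..n_experts`` given the state."""
    p = source.expert_prob(state)
    k = np.arange(source.n_experts + 1)
    return stats.binom.pmf(k, source.n_experts, p)


def _as_seedseq(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.SeedSequence(int(rng))
    raise TypeError(f"expected SeedSequence or int, got {type(rng)!r}")


def participant_stream(master_seed: int, participant_index: int) -> np.random.SeedSequence:
    """Per-participant substream of a master seed.

    The spawn-key construction makes any participant's data reproducible in
    isolation, without generating the rest of the cohort.
    """
    return np.random.SeedSequence(int(master_seed), spawn_key=(int(participant_index),))


def sample_trial(
    source: SourceSpec,
    design: ExperimentDesign,
    rng: np.random.Generator,
    *,
    participant_id: str = "p0",
    block_index: int = 0,
    trial_index: int = 0,
    phase: str = LEARNING,
) -> TrialRecord:
    """Sample state, signal and (on learning trials) feedback for one trial."""
    state = BLUE if rng.random() < design.state_prior else GREEN
    x = int(rng.binomial(source.n_experts, source.expert_prob(state)))
    feedback_Y: object = None
    if phase == LEARNING:
        fb = design.feedback
        if fb.mode == FULL:
            feedback_Y = state
        else:
            feedback_Y = int(rng.binomial(fb.n_council, fb.council_prob(state)))
    return TrialRecord(
        participant_id=participant_id,
        block_index=block_index,
        trial_index=trial_index,
        source_label=source.label,
        state=state,
        signal_X=x,
        feedback_Y=feedback_Y,
        phase=phase,
    )


def generate_block(
    source: SourceSpec,
    design: ExperimentDesign,
    rng: np.random.Generator,
    *,
    participant_id: str = "p0",
    block_index: int = 0,
) -> list[TrialRecord]:
    """One block: learning trials, then every probe signal once in random order."""
    trials: list[TrialRecord] = []
    for t in range(design.n_learning_trials):
        trials.append(
            sample_trial(
                source,
                design,
                rng,
                participant_id=participant_id,
                block_index=block_index,
                trial_index=t,
                phase=LEARNING,
            )
        )
    probe_counts = np.array(design.probe_counts(), dtype=int)
    order = rng.permutation(len(probe_counts))
    for j, idx in enumerate(order):
        # probe latent state is sampled for bookkeeping; never shown or scored
        state = BLUE if rng.random() < design.state_prior else GREEN
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                block_index=block_index,
                trial_index=design.n_learning_trials + j,
                source_label=source.label,
                state=state,
                signal_X=int(probe_counts[idx]),
                feedback_Y=None,
                phase=PROBE,
            )
        )
    return trials


def generate_experiment(
    design: ExperimentDesign,
    participant_id: str,
    rng,
) -> list[TrialRecord]:
    """One full experiment for one participant: one block per source.

    ``rng`` is a :class:`numpy.random.SeedSequence` (or int seed).  The
    sequence is spawned into one stream for the block-order shuffle plus one
    stream per block, so blocks are reproducible in isolation.
    """
    ss = _as_seedseq(rng)
    children = ss.spawn(1 + len(design.sources))
    order_rng = np.random.default_rng(children[0])
    order = order_rng.permutation(len(design.sources))
    trials: list[TrialRecord] = []
    for block_index, src_idx in enumerate(order):
        source = design.sources[src_idx]
        block_rng = np.random.default_rng(children[1 + block_index])
        trials.extend(
            generate_block(
                source,
                design,
                block_rng,
                participant_id=participant_id,
                block_index=block_index,
            )
        )
    return trials


def trials_to_frame(trials: Iterable[TrialRecord]):
    """Tidy table with one row per trial (columns = TrialRecord fields)."""
    import pandas as pd

    rows = [dataclasses.asdict(t) for t in trials]
    df = pd.DataFrame(rows, columns=[f.name for f in dataclasses.fields(TrialRecord)])
    return df


def frame_to_trials(df) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        fb = row.feedback_Y
        if fb is None or (isinstance(fb, float) and np.isnan(fb)):
            fb = None
        elif isinstance(fb, str):
            pass
        else:
            fb = int(fb)
        out.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                block_index=int(row.block_index),
                trial_index=int(row.trial_index),
                source_label=str(row.source_label),
                state=str(row.state),
                signal_X=int(row.signal_X),
                feedback_Y=fb,
                phase=str(row.phase),
            )
        )
    return out
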