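"""Parameterized human-like learner.

Wraps the ideal doubly Bayesian learner with a small set of psychologically
motivated departures from optimality, and a noisy mapping from internal
posterior to the reported slider confidence.  The nine parameters:

====================  =========================================================
``prior_mean``        shared initial mean of the beliefs about b and g
                      (a "trusting" participant starts above 0.5)
``prior_strength``    total pseudo-count of that initial belief
``updating_ratio``    eta — evidence pushing the belief toward "this source is
                      helpful" is scaled by eta; eta > 1 learns hope faster
``forget_rate``       lambda — per-trial decay of the belief back to the prior
``response_compression``  gamma — logit-scale gain from internal posterior to
                      report (gamma < 1 compresses toward 50/50)
``response_noise``    sigma_r — logit-scale Gaussian report noise
``lapse_rate``        epsilon — probability of a uniform random report
``council_weight``    w — exponent on the council likelihood in the noisy
                      condition (1 = normative use of the feedback)
``choice_temperature``  tau — softmax temperature, used only when binarizing
                      choices stochastically
====================  =========================================================

With eta = 1, lambda = 0, gamma = 1, sigma_r -> 0, epsilon = 0, w = 1 the
model's internal posteriors coincide with the ideal learner's.

The exact parameter inventory of the original fitted model is not published
in full; this module exposes the nine phenomena named above behind a freeze
mask so any subset can be held fixed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .task import (
    BLUE,
    FULL,
    GREEN,
    LEARNING,
    ExperimentDesign,
    TrialRecord,
    _as_seedseq,
    generate_experiment,
)
from .ideal import (
    BeliefGrid,
    ConjugateBelief,
    DegenerateBeliefError,
    _log_binom_pmf,
    belief_summary,
)

__all__ = [
    "ParticipantParams",
    "ResponseRecord",
    "PARAM_NAMES",
    "make_prior",
    "asymmetric_update",
    "apply_forgetting",
    "report_confidence",
    "simulate_participant",
    "internal_trajectory",
    "response_loglik",
    "responses_to_frame",
    "frame_to_responses",
]

PARAM_NAMES = (
    "prior_mean",
    "prior_strength",
    "updating_ratio",
    "forget_rate",
    "response_compression",
    "response_noise",
    "lapse_rate",
    "council_weight",
    "choice_temperature",
)

_P_CLIP = 1e-4  # internal posterior clip before logit
_REPORT_CLIP = 1e-3  # reported confidence clip (slider endpoints)


@dataclass(frozen=True)
class ParticipantParams:
    prior_mean: float = 0.5
    prior_strength: float = 2.0
    updating_ratio: float = 1.0
    forget_rate: float = 0.0
    response_compression: float = 1.0
    response_noise: float = 0.5
    lapse_rate: float = 0.0
    council_weight: float = 1.0
    choice_temperature: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_mean < 1.0):
            raise ValueError("prior_mean must lie in (0, 1)")
        if self.prior_strength <= 0:
            raise ValueError("prior_strength must be positive")
        if self.updating_ratio <= 0:
            raise ValueError("updating_ratio must be positive")
        if not (0.0 <= self.forget_rate <= 1.0):
            raise ValueError("forget_rate must lie in [0, 1]")
        if self.response_compression <= 0:
            raise ValueError("response_compression must be positive")
        if self.response_noise <= 0:
            raise ValueError("response_noise must be positive")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not (0.0 <= self.council_weight <= 1.0):
            raise ValueError("council_weight must lie in [0, 1]")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be positive")

    @classmethod
    def ideal(cls, response_noise: float = 1e-6) -> "ParticipantParams":
        """Neutral settings whose internal posteriors equal the ideal learner."""
        return cls(prior_mean=0.5, prior_strength=2.0, response_noise=response_noise)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ParticipantParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ResponseRecord:
    """One trial's reported confidence(s) and binarized choice."""

    participant_id: str
    block_index: int
    trial_index: int
    confidence: float
    revised_confidence: float | None
    binarized_choice: str


def make_prior(params: ParticipantParams, kind: str = "conjugate", resolution: int = 61):
    """Initial belief: independent Beta(m·s, (1−m)·s) on each of b and g."""
    a = params.prior_mean * params.prior_strength
    b = (1.0 - params.prior_mean) * params.prior_strength
    if kind == "conjugate":
        return ConjugateBelief(a, b, a, b)
    if kind == "grid":
        return BeliefGrid.from_beta((a, b), (a, b), resolution)
    raise ValueError(f"unknown belief kind {kind!r}")


# ---------------------------------------------------------------------------
# asymmetric updating
# ---------------------------------------------------------------------------

def _asym_update_conjugate(
    belief: ConjugateBelief, X: int, revealed_state: str, eta: float, n: int
) -> ConjugateBelief:
    # endorsements consistent with the revealed state push the belief toward
    # "helpful" and are scaled by eta; inconsistent ones count at weight 1
    if revealed_state == BLUE:
        return dataclasses.replace(
            belief, alpha_b=belief.alpha_b + eta * X, beta_b=belief.beta_b + (n - X)
        )
    return dataclasses.replace(
        belief, alpha_g=belief.alpha_g + eta * (n - X), beta_g=belief.beta_g + X
    )


def _asym_branch_logliks(grid: BeliefGrid, X: int, n: int, eta: float):
    """Per-cell log-likelihood of X under each state branch, eta-reweighted."""
    lb = np.log(grid.b_axis)
    l1b = np.log1p(-grid.b_axis)
    lg = np.log(grid.g_axis)
    l1g = np.log1p(-grid.g_axis)
    # blue branch depends on b: X confirming endorsements scaled by eta
    blue = (eta * X) * lb + (n - X) * l1b
    # green branch depends on g: n-X confirming endorsements scaled by eta
    green = (eta * (n - X)) * lg + X * l1g
    return blue[:, None], green[None, :]


def _asym_update_grid_full(
    grid: BeliefGrid, X: int, revealed_state: str, eta: float, n: int
) -> BeliefGrid:
    blue, green = _asym_branch_logliks(grid, X, n, eta)
    with np.errstate(divide="ignore"):
        logm = np.log(grid.joint_mass, out=np.full_like(grid.joint_mass, -np.inf),
                      where=grid.joint_mass > 0)
    logm = logm + (blue + np.zeros((1, grid.g_axis.size)) if revealed_state == BLUE
                   else green + np.zeros((grid.b_axis.size, 1)))
    total = special.logsumexp(logm)
    if not np.isfinite(total):
        raise DegenerateBeliefError("asymmetric update produced zero mass")
    return BeliefGrid(grid.b_axis, grid.g_axis, np.exp(logm - total), normalize=False)


def _asym_update_grid_noisy(
    grid: BeliefGrid,
    X: int,
    Y: int,
    feedback,
    state_prior: float,
    eta: float,
    w: float,
    n: int,
) -> BeliefGrid:
    blue, green = _asym_branch_logliks(grid, X, n, eta)
    with np.errstate(divide="ignore"):
        log_y_blue = math.log(stats.binom.pmf(Y, feedback.n_council, feedback.b_Y))
        log_y_green = math.log(stats.binom.pmf(Y, feedback.n_council, 1.0 - feedback.b_Y))
        logm = np.log(grid.joint_mass, out=np.full_like(grid.joint_mass, -np.inf),
                      where=grid.joint_mass > 0)
    branch_blue = blue + w * log_y_blue + math.log(state_prior)
    branch_green = green + w * log_y_green + math.log1p(-state_prior)
    logm = logm + np.logaddexp(branch_blue, branch_green)
    total = special.logsumexp(logm)
    if not np.isfinite(total):
        raise DegenerateBeliefError("asymmetric update produced zero mass")
    return BeliefGrid(grid.b_axis, grid.g_axis, np.exp(logm - total), normalize=False)


def asymmetric_update(
    belief,
    X: int,
    feedback_value,
    params: ParticipantParams,
    *,
    n: int = 5,
    feedback_config=None,
    state_prior: float = 0.5,
):
    """Eta-reweighted belief update for one learning trial.

    ``feedback_value`` is the revealed state (full feedback) or the council
    count (noisy feedback; requires ``feedback_config``).  With eta = 1 and
    council_weight = 1 this is the normative update.
    """
    eta = params.updating_ratio
    if feedback_value in (BLUE, GREEN):
        if isinstance(belief, ConjugateBelief):
            return _asym_update_conjugate(belief, X, feedback_value, eta, n)
        return _asym_update_grid_full(belief, X, feedback_value, eta, n)
    if feedback_config is None:
        raise ValueError("noisy update requires feedback_config")
    if not isinstance(belief, BeliefGrid):
        raise TypeError("noisy updates require a BeliefGrid belief")
    return _asym_update_grid_noisy(
        belief, X, int(feedback_value), feedback_config, state_prior,
        eta, params.council_weight, n,
    )


def apply_forgetting(belief, prior_belief, params: ParticipantParams):
    """Decay the belief toward the initial prior at rate lambda per trial."""
    lam = params.forget_rate
    if lam == 0.0:
        return belief
    if isinstance(belief, ConjugateBelief):
        keep = 1.0 - lam
        return ConjugateBelief(
            keep * belief.alpha_b + lam * prior_belief.alpha_b,
            keep * belief.beta_b + lam * prior_belief.beta_b,
            keep * belief.alpha_g + lam * prior_belief.alpha_g,
            keep * belief.beta_g + lam * prior_belief.beta_g,
        )
    mass = (1.0 - lam) * belief.joint_mass + lam * prior_belief.joint_mass
    return BeliefGrid(belief.b_axis, belief.g_axis, mass)


# ---------------------------------------------------------------------------
# response mapping
# ---------------------------------------------------------------------------

def _clip_internal(p: float) -> float:
    return min(max(p, _P_CLIP), 1.0 - _P_CLIP)


def report_confidence(internal_p: float, params: ParticipantParams, rng: np.random.Generator) -> float:
    """Map an internal posterior to a reported slider confidence.

    With probability epsilon the report is uniform (lapse); otherwise the
    report's logit is Gaussian around gamma times the internal logit.
    """
    if rng.random() < params.lapse_rate:
        return float(rng.uniform())
    mu = params.response_compression * special.logit(_clip_internal(internal_p))
    z = mu + params.response_noise * rng.standard_normal()
    return float(np.clip(special.expit(z), _REPORT_CLIP, 1.0 - _REPORT_CLIP))


def binarize_choice(confidence: float, rng: np.random.Generator, tau: float | None = None) -> str:
    """Blue iff confidence > 0.5; a tie is broken by a fair coin.

    If ``tau`` is given the choice is instead sampled from a softmax on the
    confidence logit with temperature tau.
    """
    if tau is not None:
        p_blue = float(special.expit(special.logit(_clip_internal(confidence)) / tau))
        return BLUE if rng.random() < p_blue else GREEN
    if confidence > 0.5:
        return BLUE
    if confidence < 0.5:
        return GREEN
    return BLUE if rng.random() < 0.5 else GREEN


# ---------------------------------------------------------------------------
# internal posterior trajectory (deterministic given params and trials)
# ---------------------------------------------------------------------------

def _conj_state_p(a_b, b_b, a_g, b_g, x, n, state_prior):
    """Beta-binomial state posterior, scalar fast path (lgamma arithmetic)."""
    lg = math.lgamma
    # blue branch: success prob b ~ Beta(a_b, b_b)
    lblue = (lg(a_b + x) + lg(b_b + n - x) - lg(a_b + b_b + n)) - (
        lg(a_b) + lg(b_b) - lg(a_b + b_b)
    )
    # green branch: success prob 1-g, g ~ Beta(a_g, b_g) => 1-g ~ Beta(b_g, a_g)
    lgreen = (lg(b_g + x) + lg(a_g + n - x) - lg(a_g + b_g + n)) - (
        lg(a_g) + lg(b_g) - lg(a_g + b_g)
    )
    log_odds = lblue - lgreen + math.log(state_prior) - math.log1p(-state_prior)
    return 1.0 / (1.0 + math.exp(-log_odds))


def _council_log_lr_scalar(Y: int, feedback) -> float:
    nc, bY = feedback.n_council, feedback.b_Y
    return (2 * Y - nc) * (math.log(bY) - math.log1p(-bY))


def _trajectory_full_block(block, params, n, state_prior):
    """Per-trial internal posteriors for one full-feedback block (conjugate)."""
    pa = params.prior_mean * params.prior_strength
    pb = (1.0 - params.prior_mean) * params.prior_strength
    a_b, b_b, a_g, b_g = pa, pb, pa, pb
    eta, lam = params.updating_ratio, params.forget_rate
    out = []
    summaries = []
    for trial in block:
        p = _conj_state_p(a_b, b_b, a_g, b_g, trial.signal_X, n, state_prior)
        if trial.phase == LEARNING:
            x = trial.signal_X
            if trial.feedback_Y == BLUE:
                a_b, b_b = a_b + eta * x, b_b + (n - x)
            else:
                a_g, b_g = a_g + eta * (n - x), b_g + x
            if lam > 0.0:
                keep = 1.0 - lam
                a_b = keep * a_b + lam * pa
                b_b = keep * b_b + lam * pb
                a_g = keep * a_g + lam * pa
                b_g = keep * b_g + lam * pb
        out.append((p, None))
        summaries.append(0.5 * (a_b / (a_b + b_b) + a_g / (a_g + b_g)))
    return out, summaries


def _trajectory_noisy_block(block, params, n, state_prior, feedback, resolution):
    """Per-trial internal (initial, revised) posteriors for one noisy block."""
    prior = make_prior(params, "grid", resolution)
    grid = prior.copy()
    out = []
    summaries = []
    council_lr = {
        y: _council_log_lr_scalar(y, feedback) for y in range(feedback.n_council + 1)
    }
    for trial in block:
        x = trial.signal_X
        log_blue = _log_binom_pmf(x, n, grid.b_axis)
        log_green = _log_binom_pmf(x, n, 1.0 - grid.g_axis)
        lb = special.logsumexp(log_blue, b=grid.marginal_b)
        lgr = special.logsumexp(log_green, b=grid.marginal_g)
        log_odds = (lb - lgr) + math.log(state_prior) - math.log1p(-state_prior)
        p = float(special.expit(log_odds))
        revised = None
        if trial.phase == LEARNING:
            y = int(trial.feedback_Y)
            revised = float(
                special.expit(log_odds + params.council_weight * council_lr[y])
            )
            grid = _asym_update_grid_noisy(
                grid, x, y, feedback, state_prior,
                params.updating_ratio, params.council_weight, n,
            )
            grid = apply_forgetting(grid, prior, params)
        out.append((p, revised))
        summaries.append(belief_summary(grid))
    return out, summaries


def internal_trajectory(
    trials: Sequence[TrialRecord],
    params: ParticipantParams,
    design: ExperimentDesign,
    resolution: int = 61,
    with_summaries: bool = False,
):
    """Noise-free internal posteriors for every trial, block by block.

    The belief resets to the participant's prior at each block boundary
    (each source is learned independently).  Returns a list of
    ``(confidence, revised_confidence)`` pairs aligned with ``trials``;
    ``revised_confidence`` is ``None`` outside noisy-condition learning
    trials.  With ``with_summaries`` also returns the per-trial belief
    summary (E[b]+E[g])/2 after the trial's update.
    """
    n = design.n_experts
    fb = design.feedback
    results: list = []
    summaries: list = []
    # group consecutive trials by block
    block: list[TrialRecord] = []
    blocks: list[list[TrialRecord]] = []
    for trial in trials:
        if block and trial.block_index != block[-1].block_index:
            blocks.append(block)
            block = []
        block.append(trial)
    if block:
        blocks.append(block)
    for blk in blocks:
        if fb.mode == FULL:
            res, summ = _trajectory_full_block(blk, params, n, design.state_prior)
        else:
            res, summ = _trajectory_noisy_block(
                blk, params, n, design.state_prior, fb, resolution
            )
        results.extend(res)
        summaries.extend(summ)
    if with_summaries:
        return results, summaries
    return results


def simulate_participant(
    design: ExperimentDesign,
    params: ParticipantParams,
    rng,
    participant_id: str = "p0",
    resolution: int = 61,
) -> tuple[list[TrialRecord], list[ResponseRecord]]:
    """Generate one participant's trials and simulated responses.

    ``rng`` is a SeedSequence (or int); it is spawned into a trial stream and
    a response-noise stream so trial structure and report noise are
    independently reproducible.
    """
    ss = _as_seedseq(rng)
    trial_ss, noise_ss = ss.spawn(2)
    trials = generate_experiment(design, participant_id, trial_ss)
    noise_rng = np.random.default_rng(noise_ss)
    internal = internal_trajectory(trials, params, design, resolution)
    responses = []
    for trial, (p, revised) in zip(trials, internal):
        conf = report_confidence(p, params, noise_rng)
        rev = None
        if revised is not None:
            rev = report_confidence(revised, params, noise_rng)
        responses.append(
            ResponseRecord(
                participant_id=trial.participant_id,
                block_index=trial.block_index,
                trial_index=trial.trial_index,
                confidence=conf,
                revised_confidence=rev,
                binarized_choice=binarize_choice(conf, noise_rng),
            )
        )
    return trials, responses


# ---------------------------------------------------------------------------
# response likelihood
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _rating_logdensities(observed, internal, params):
    """Vector of log densities of observed confidences under the report model."""
    c = np.clip(np.asarray(observed, dtype=float), _REPORT_CLIP, 1.0 - _REPORT_CLIP)
    p = np.clip(np.asarray(internal, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    z = special.logit(c)
    mu = params.response_compression * special.logit(p)
    sig = params.response_noise
    log_norm = -0.5 * ((z - mu) / sig) ** 2 - math.log(sig) - _LOG_SQRT_2PI
    log_ln = log_norm - np.log(c) - np.log1p(-c)  # logit-normal density in c
    eps = params.lapse_rate
    if eps == 0.0:
        return log_ln
    if eps == 1.0:
        return np.zeros_like(log_ln)
    return np.logaddexp(math.log(eps), math.log1p(-eps) + log_ln)


def response_loglik(
    params: ParticipantParams,
    trials: Sequence[TrialRecord],
    responses: Sequence[ResponseRecord],
    design: ExperimentDesign,
    resolution: int = 61,
) -> float:
    """Total log density of the observed confidences under the model.

    In the noisy condition both the initial and the revised rating of each
    learning trial contribute.  Deterministic given its arguments.
    """
    if len(trials) != len(responses):
        raise ValueError("trials and responses have different lengths")
    for trial, resp in zip(trials, responses):
        if (trial.block_index, trial.trial_index) != (resp.block_index, resp.trial_index):
            raise ValueError(
                f"misaligned logs at block {trial.block_index} trial {trial.trial_index}"
            )
    internal = internal_trajectory(trials, params, design, resolution)
    obs, ps = [], []
    for resp, (p, revised) in zip(responses, internal):
        obs.append(resp.confidence)
        ps.append(p)
        if revised is not None:
            if resp.revised_confidence is None:
                raise ValueError("missing revised confidence on a noisy learning trial")
            obs.append(resp.revised_confidence)
            ps.append(revised)
    return float(np.sum(_rating_logdensities(obs, ps, params)))


# ---------------------------------------------------------------------------
# tabular round-tripping
# ---------------------------------------------------------------------------

def responses_to_frame(responses: Iterable[ResponseRecord]):
    import pandas as pd

    rows = [dataclasses.asdict(r) for r in responses]
    df = pd.DataFrame(
        rows, columns=[f.name for f in dataclasses.fields(ResponseRecord)]
    )
    # absent revisions are NaN so the column stays float-typed
    df["revised_confidence"] = df["revised_confidence"].astype(float)
    return df


def frame_to_responses(df) -> list[ResponseRecord]:
    out = []
    for row in df.itertuples(index=False):
        rev = row.revised_confidence
        if rev is not None and isinstance(rev, float) and math.isnan(rev):
            rev = None
        out.append(
            ResponseRecord(
                participant_id=str(row.participant_id),
                block_index=int(row.block_index),
                trial_index=int(row.trial_index),
                confidence=float(row.confidence),
                revised_confidence=None if rev is None else float(rev),
                binarized_choice=str(row.binarized_choice),
            )
        )
    return out
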