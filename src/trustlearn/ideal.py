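"""The doubly Bayesian ideal learner.

The agent simultaneously infers the latent state of each trial and the
reliability pair ``(b, g)`` of the source reporting on it.  The state
posterior marginalizes the signal likelihood over the current belief about
``(b, g)``; the belief about ``(b, g)`` is then updated with the trial's
signal and feedback.

Two belief representations are provided:

* :class:`ConjugateBelief` — independent Beta distributions on ``b`` and
  ``g``.  Exact under *full* feedback, where the update is a closed-form
  beta-binomial step: the revealed state routes the five endorsements into
  the pseudo-counts of exactly one of the two parameters.
* :class:`BeliefGrid` — a discrete joint distribution on a grid over
  ``(0,1)²``.  Required under *noisy* feedback, where marginalizing over the
  unknown state couples ``b`` and ``g`` and no closed form exists.

All grid likelihood products are accumulated in log space and renormalized
once per update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .task import (
    BLUE,
    FULL,
    GREEN,
    LEARNING,
    NOISY,
    ExperimentDesign,
    FeedbackConfig,
    TrialRecord,
)

__all__ = [
    "ConjugateBelief",
    "BeliefGrid",
    "init_grid",
    "state_posterior",
    "revised_state_posterior",
    "update_full",
    "update_noisy",
    "run_optimal_agent",
    "belief_summary",
]


class DegenerateBeliefError(ValueError):
    """Raised when a belief update or query would divide by zero mass."""


@dataclass(frozen=True)
class ConjugateBelief:
    """Independent Beta(alpha_b, beta_b) on b and Beta(alpha_g, beta_g) on g."""

    alpha_b: float
    beta_b: float
    alpha_g: float
    beta_g: float

    def __post_init__(self) -> None:
        for name in ("alpha_b", "beta_b", "alpha_g", "beta_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mean_b(self) -> float:
        return self.alpha_b / (self.alpha_b + self.beta_b)

    @property
    def mean_g(self) -> float:
        return self.alpha_g / (self.alpha_g + self.beta_g)

    @property
    def sd_b(self) -> float:
        a, b = self.alpha_b, self.beta_b
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    @property
    def sd_g(self) -> float:
        a, b = self.alpha_g, self.beta_g
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    @classmethod
    def flat(cls) -> "ConjugateBelief":
        return cls(1.0, 1.0, 1.0, 1.0)


class BeliefGrid:
    """Joint distribution over (b, g) on a product grid inside (0,1)².

    ``joint_mass[i, j]`` is the probability mass at ``(b_axis[i], g_axis[j])``.
    Axes are strictly increasing and exclude the endpoints 0 and 1.
    """

    __slots__ = ("b_axis", "g_axis", "joint_mass")

    def __init__(self, b_axis, g_axis, joint_mass, *, normalize: bool = True):
        b_axis = np.asarray(b_axis, dtype=float)
        g_axis = np.asarray(g_axis, dtype=float)
        joint_mass = np.asarray(joint_mass, dtype=float)
        for name, ax in (("b_axis", b_axis), ("g_axis", g_axis)):
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-d array")
            if np.any(ax <= 0.0) or np.any(ax >= 1.0):
                raise ValueError(f"{name} values must lie strictly inside (0, 1)")
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if joint_mass.shape != (b_axis.size, g_axis.size):
            raise ValueError("joint_mass shape must be (len(b_axis), len(g_axis))")
        if np.any(joint_mass < 0):
            raise ValueError("joint_mass must be non-negative")
        total = joint_mass.sum()
        if normalize:
            if total <= 0 or not np.isfinite(total):
                raise DegenerateBeliefError("belief has zero or non-finite total mass")
            joint_mass = joint_mass / total
        self.b_axis = b_axis
        self.g_axis = g_axis
        self.joint_mass = joint_mass

    # -- constructors ---------------------------------------------------
    @staticmethod
    def midpoint_axis(resolution: int) -> np.ndarray:
        return (np.arange(resolution) + 0.5) / resolution

    @classmethod
    def from_beta(
        cls,
        ab_b: tuple[float, float],
        ab_g: tuple[float, float],
        resolution: int = 61,
    ) -> "BeliefGrid":
        """Grid approximation of independent Beta priors at cell midpoints."""
        if resolution < 11:
            raise ValueError("resolution must be >= 11")
        axis = cls.midpoint_axis(resolution)
        dens_b = stats.beta.pdf(axis, *ab_b)
        dens_g = stats.beta.pdf(axis, *ab_g)
        return cls(axis, axis, np.outer(dens_b, dens_g))

    @classmethod
    def flat(cls, resolution: int = 61) -> "BeliefGrid":
        return cls.from_beta((1.0, 1.0), (1.0, 1.0), resolution)

    @classmethod
    def point_mass(cls, b: float, g: float) -> "BeliefGrid":
        """Degenerate single-cell belief — the 'known source' limit."""
        return cls(np.array([b]), np.array([g]), np.array([[1.0]]))

    # -- summaries ------------------------------------------------------
    @property
    def marginal_b(self) -> np.ndarray:
        return self.joint_mass.sum(axis=1)

    @property
    def marginal_g(self) -> np.ndarray:
        return self.joint_mass.sum(axis=0)

    @property
    def mean_b(self) -> float:
        return float(self.marginal_b @ self.b_axis)

    @property
    def mean_g(self) -> float:
        return float(self.marginal_g @ self.g_axis)

    @property
    def sd_b(self) -> float:
        m = self.mean_b
        return float(np.sqrt(self.marginal_b @ (self.b_axis - m) ** 2))

    @property
    def sd_g(self) -> float:
        m = self.mean_g
        return float(np.sqrt(self.marginal_g @ (self.g_axis - m) ** 2))

    def covariance_bg(self) -> float:
        """Cov(b, g) under the joint belief; nonzero once updates couple them."""
        db = self.b_axis - self.mean_b
        dg = self.g_axis - self.mean_g
        return float(db @ self.joint_mass @ dg)

    def copy(self) -> "BeliefGrid":
        return BeliefGrid(self.b_axis, self.g_axis, self.joint_mass.copy(), normalize=False)


def init_grid(
    prior_b: tuple[float, float] = (1.0, 1.0),
    prior_g: tuple[float, float] = (1.0, 1.0),
    resolution: int = 61,
) -> BeliefGrid:
    """Grid belief initialized from per-parameter beta shape pairs."""
    return BeliefGrid.from_beta(prior_b, prior_g, resolution)


def _log_binom_pmf(x: int, n: int, p: np.ndarray) -> np.ndarray:
    """log Binomial(x; n, p) for an array of probabilities p in (0,1)."""
    p = np.asarray(p, dtype=float)
    logc = special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
    return logc + x * np.log(p) + (n - x) * np.log1p(-p)


def _predictive_logpmf_conjugate(belief: ConjugateBelief, x: int, n: int, state: str) -> float:
    """log P(X=x | state) marginalized over the beta belief (beta-binomial)."""
    logc = special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
    if state == BLUE:
        a, b = belief.alpha_b, belief.beta_b
        # success prob is b itself
        return float(logc + special.betaln(a + x, b + n - x) - special.betaln(a, b))
    # green: success prob is 1-g, and g ~ Beta(alpha_g, beta_g) => 1-g ~ Beta(beta_g, alpha_g)
    a, b = belief.beta_g, belief.alpha_g
    return float(logc + special.betaln(a + x, b + n - x) - special.betaln(a, b))


def _branch_logliks_grid(belief: BeliefGrid, x: int, n: int) -> tuple[float, float]:
    """log of sum_{b,g} mass * P(X|state) for the blue and green branches."""
    log_blue = _log_binom_pmf(x, n, belief.b_axis)  # over b_axis
    log_green = _log_binom_pmf(x, n, 1.0 - belief.g_axis)  # over g_axis
    mb = belief.marginal_b
    mg = belief.marginal_g
    with np.errstate(divide="ignore"):
        lb = special.logsumexp(log_blue, b=mb)
        lg = special.logsumexp(log_green, b=mg)
    return float(lb), float(lg)


def state_posterior(
    belief,
    X: int,
    n: int = 5,
    state_prior: float = 0.5,
) -> float:
    """Posterior probability that the state is blue given signal ``X``.

    Marginalizes the binomial signal likelihood over the agent's current
    belief about (b, g) and combines with the state prior.
    """
    if not (0 <= X <= n):
        raise ValueError(f"signal X={X} outside 0..{n}")
    if isinstance(belief, ConjugateBelief):
        lb = _predictive_logpmf_conjugate(belief, X, n, BLUE)
        lg = _predictive_logpmf_conjugate(belief, X, n, GREEN)
    elif isinstance(belief, BeliefGrid):
        if belief.joint_mass.sum() <= 0:
            raise DegenerateBeliefError("belief has zero total mass")
        lb, lg = _branch_logliks_grid(belief, X, n)
    else:
        raise TypeError(f"unsupported belief type {type(belief)!r}")
    log_odds = (lb + np.log(state_prior)) - (lg + np.log1p(-state_prior))
    return float(special.expit(log_odds))


def _council_log_odds(Y: int, feedback: FeedbackConfig) -> float:
    """log [ P(Y|blue) / P(Y|green) ] for the Independent Council signal."""
    lb = _log_binom_pmf(Y, feedback.n_council, np.array([feedback.b_Y]))[0]
    lg = _log_binom_pmf(Y, feedback.n_council, np.array([1.0 - feedback.b_Y]))[0]
    return float(lb - lg)


def revised_state_posterior(
    belief,
    X: int,
    Y: int,
    feedback: FeedbackConfig,
    n: int = 5,
    state_prior: float = 0.5,
    council_weight: float = 1.0,
) -> float:
    """State posterior after both the source signal and the council signal.

    Each state branch is additionally weighted by the council likelihood
    (optionally raised to ``council_weight``; 1 is normative).
    """
    if feedback.mode != NOISY:
        raise ValueError("revised_state_posterior requires noisy-mode feedback")
    p = state_posterior(belief, X, n, state_prior)
    log_odds = special.logit(p) + council_weight * _council_log_odds(Y, feedback)
    return float(special.expit(log_odds))


def update_full(belief, X: int, revealed_state: str, n: int = 5):
    """Belief update under full feedback (revealed state).

    Conjugate form: the revealed state routes the endorsement counts into the
    pseudo-counts of exactly one reliability parameter — ``b`` when blue,
    ``g`` when green.  Grid form: multiply by the revealed-state likelihood
    and renormalize.
    """
    if revealed_state not in (BLUE, GREEN):
        raise ValueError(f"invalid revealed state {revealed_state!r}")
    if isinstance(belief, ConjugateBelief):
        if revealed_state == BLUE:
            return replace(belief, alpha_b=belief.alpha_b + X, beta_b=belief.beta_b + (n - X))
        return replace(belief, alpha_g=belief.alpha_g + (n - X), beta_g=belief.beta_g + X)
    if isinstance(belief, BeliefGrid):
        logm = np.log(belief.joint_mass, out=np.full_like(belief.joint_mass, -np.inf),
                      where=belief.joint_mass > 0)
        if revealed_state == BLUE:
            logm = logm + _log_binom_pmf(X, n, belief.b_axis)[:, None]
        else:
            logm = logm + _log_binom_pmf(X, n, 1.0 - belief.g_axis)[None, :]
        return _renormalized(belief, logm)
    raise TypeError(f"unsupported belief type {type(belief)!r}")


def _renormalized(belief: BeliefGrid, log_mass: np.ndarray) -> BeliefGrid:
    total = special.logsumexp(log_mass)
    if not np.isfinite(total):
        raise DegenerateBeliefError("belief update produced zero total mass")
    return BeliefGrid(belief.b_axis, belief.g_axis, np.exp(log_mass - total), normalize=False)


def update_noisy(
    belief: BeliefGrid,
    X: int,
    Y: int,
    feedback: FeedbackConfig,
    state_prior: float = 0.5,
    n: int = 5,
    council_weight: float = 1.0,
) -> BeliefGrid:
    """Semi-supervised belief update under noisy (council) feedback.

    The joint mass is multiplied by the state-marginalized likelihood

        sum_s P(X | s; b, g) · P(Y | s)^w · p(s)

    so the council evidence only *weights* the two state branches instead of
    selecting one; this couples b and g and is why the joint grid is needed.
    With ``b_Y = 1`` the council branch collapses to an indicator and the
    update equals :func:`update_full`.
    """
    if not isinstance(belief, BeliefGrid):
        raise TypeError("update_noisy requires a BeliefGrid belief")
    if feedback.mode != NOISY:
        raise ValueError("update_noisy requires noisy-mode feedback")
    log_x_blue = _log_binom_pmf(X, n, belief.b_axis)[:, None]  # depends on b
    log_x_green = _log_binom_pmf(X, n, 1.0 - belief.g_axis)[None, :]  # depends on g
    with np.errstate(divide="ignore"):
        log_y_blue = np.log(stats.binom.pmf(Y, feedback.n_council, feedback.b_Y))
        log_y_green = np.log(stats.binom.pmf(Y, feedback.n_council, 1.0 - feedback.b_Y))
        log_prior_blue = np.log(state_prior)
        log_prior_green = np.log1p(-state_prior)
        logm = np.log(belief.joint_mass, out=np.full_like(belief.joint_mass, -np.inf),
                      where=belief.joint_mass > 0)
    branch_blue = log_x_blue + council_weight * log_y_blue + log_prior_blue
    branch_green = log_x_green + council_weight * log_y_green + log_prior_green
    logm = logm + np.logaddexp(branch_blue, branch_green)
    return _renormalized(belief, logm)


def belief_summary(belief) -> float:
    """Mean over the two marginal reliability expectations, (E[b] + E[g]) / 2."""
    return 0.5 * (belief.mean_b + belief.mean_g)


def run_optimal_agent(
    trials: list[TrialRecord],
    design: ExperimentDesign,
    resolution: int = 61,
    prior: tuple[tuple[float, float], tuple[float, float]] | None = None,
):
    """Run the parameter-free normative agent over one block of trials.

    Uses the conjugate machinery under full feedback and the joint grid under
    noisy feedback.  Probe trials are scored with the frozen end-of-learning
    belief and trigger no update.  Returns a list of per-trial dicts with the
    confidence (and revised confidence in noisy mode) plus the belief
    trajectory summaries *after* the trial's update.
    """
    fb = design.feedback
    prior_b, prior_g = prior if prior is not None else ((1.0, 1.0), (1.0, 1.0))
    if fb.mode == FULL:
        belief = ConjugateBelief(prior_b[0], prior_b[1], prior_g[0], prior_g[1])
    else:
        belief = init_grid(prior_b, prior_g, resolution)
    n = design.n_experts
    out = []
    for trial in trials:
        conf = state_posterior(belief, trial.signal_X, n, design.state_prior)
        revised = None
        if trial.phase == LEARNING:
            if fb.mode == FULL:
                belief = update_full(belief, trial.signal_X, trial.feedback_Y, n)
            else:
                revised = revised_state_posterior(
                    belief, trial.signal_X, trial.feedback_Y, fb, n, design.state_prior
                )
                belief = update_noisy(
                    belief, trial.signal_X, trial.feedback_Y, fb, design.state_prior, n
                )
        out.append(
            {
                "block_index": trial.block_index,
                "trial_index": trial.trial_index,
                "phase": trial.phase,
                "signal_X": trial.signal_X,
                "confidence": conf,
                "revised_confidence": revised,
                "mean_b": belief.mean_b,
                "mean_g": belief.mean_g,
                "sd_b": belief.sd_b,
                "sd_g": belief.sd_g,
                "belief_summary": belief_summary(belief),
            }
        )
    return out
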