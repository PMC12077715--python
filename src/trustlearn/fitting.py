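"""Maximum-likelihood estimation of participant parameters.

The response log-likelihood is cheap but non-smooth near the corners of the
forgetting and updating-ratio ranges, so fitting uses bounded derivative-free
local search (Powell) from several quasi-random starting points, on
transformed scales: logit for probability-type parameters, log for positive
scalars.  A profile-curvature guardrail flags directions in which the
likelihood is locally flat — several parameters are only weakly separable
from one another in this model class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .behavior import (
    PARAM_NAMES,
    ParticipantParams,
    ResponseRecord,
    internal_trajectory,
    report_confidence,
    response_loglik,
)
from .task import ExperimentDesign, TrialRecord, _as_seedseq

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "fit_participant",
    "posterior_predictive",
    "recovery_study",
    "RecoveryReport",
    "DEFAULT_BOUNDS",
    "DEFAULT_FREE",
]


class FitError(RuntimeError):
    """All optimization restarts failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


#: Optimization bounds on the natural scale of each parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "prior_mean": (0.02, 0.98),
    "prior_strength": (0.2, 60.0),
    "updating_ratio": (0.05, 10.0),
    "forget_rate": (1e-4, 0.9),
    "response_compression": (0.1, 10.0),
    "response_noise": (0.01, 5.0),
    "lapse_rate": (1e-4, 0.5),
    "council_weight": (0.01, 0.999),
    "choice_temperature": (0.05, 20.0),
}

# probability-type parameters go through logit, positive scalars through log
_LOGIT_PARAMS = {"prior_mean", "forget_rate", "lapse_rate", "council_weight"}

#: Default free subset: the parameters that shape the confidence likelihood
#: most directly and remain identifiable from a single participant's log.
DEFAULT_FREE = (
    "prior_mean",
    "prior_strength",
    "updating_ratio",
    "forget_rate",
    "response_noise",
)

_CURVATURE_FLAT = 1e-3  # |d2 logL / d theta2| below this flags a flat direction


def _to_unconstrained(name: str, value: float) -> float:
    lo, hi = DEFAULT_BOUNDS[name]
    value = min(max(value, lo), hi)
    if name in _LOGIT_PARAMS:
        return float(special.logit(value))
    return math.log(value)


def _to_constrained(name: str, z: float) -> float:
    lo, hi = DEFAULT_BOUNDS[name]
    if name in _LOGIT_PARAMS:
        v = float(special.expit(z))
    else:
        v = math.exp(min(z, 50.0))
    return min(max(v, lo), hi)


@dataclass(frozen=True)
class FitConfig:
    free: tuple[str, ...] = DEFAULT_FREE
    n_restarts: int = 8
    seed: int = 0
    resolution: int = 61
    maxiter: int = 60
    xtol: float = 1e-4
    ftol: float = 1e-6


@dataclass
class FitResult:
    best_params: ParticipantParams
    log_likelihood: float
    n_restarts: int
    converged: list[bool]
    restart_logliks: list[float]
    fixed_mask: dict[str, float]
    curvature: dict[str, float] = field(default_factory=dict)
    flat_directions: tuple[str, ...] = ()


def _make_objective(trials, responses, design, base: ParticipantParams, free, resolution):
    def negloglik(z: np.ndarray) -> float:
        kwargs = {name: _to_constrained(name, zi) for name, zi in zip(free, z)}
        params = base.replace(**kwargs)
        try:
            return -response_loglik(params, trials, responses, design, resolution)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    return negloglik


def fit_participant(
    trials: list[TrialRecord],
    responses: list[ResponseRecord],
    design: ExperimentDesign,
    config: FitConfig = FitConfig(),
    base_params: ParticipantParams | None = None,
) -> FitResult:
    """Multi-start bounded MLE of the free parameters for one participant.

    ``base_params`` supplies values for every frozen parameter (defaults to
    the neutral vector).  Deterministic given ``config.seed``.
    """
    if not trials:
        raise ValueError("empty trial log")
    base = base_params if base_params is not None else ParticipantParams()
    free = tuple(config.free)
    for name in free:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    if not free:
        # fully frozen fit: the likelihood at the base vector, exactly
        ll = response_loglik(base, trials, responses, design, config.resolution)
        return FitResult(
            best_params=base,
            log_likelihood=ll,
            n_restarts=0,
            converged=[],
            restart_logliks=[],
            fixed_mask={name: getattr(base, name) for name in PARAM_NAMES},
        )
    objective = _make_objective(trials, responses, design, base, free, config.resolution)

    # starting points: the base vector plus scrambled-Sobol points in the
    # transformed bounding box
    z0 = np.array([_to_unconstrained(name, getattr(base, name)) for name in free])
    lo = np.array([_to_unconstrained(name, DEFAULT_BOUNDS[name][0] * 1.02 + 1e-6) for name in free])
    hi = np.array([_to_unconstrained(name, DEFAULT_BOUNDS[name][1] * 0.98) for name in free])
    starts = [z0]
    if config.n_restarts > 1:
        sob = stats.qmc.Sobol(d=len(free), scramble=True, rng=np.random.default_rng(config.seed))
        m = max(1, math.ceil(math.log2(config.n_restarts - 1)))
        u = sob.random_base2(m)[: config.n_restarts - 1]
        for row in u:
            starts.append(lo + row * (hi - lo))

    best = None
    converged, logliks, diagnostics = [], [], []
    for z_start in starts:
        try:
            res = optimize.minimize(
                objective,
                z_start,
                method="Powell",
                options={
                    "maxiter": config.maxiter,
                    "xtol": config.xtol,
                    "ftol": config.ftol,
                },
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(repr(exc))
            converged.append(False)
            logliks.append(-np.inf)
            continue
        converged.append(bool(res.success))
        logliks.append(-float(res.fun))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("all optimization restarts failed", diagnostics)

    kwargs = {name: _to_constrained(name, zi) for name, zi in zip(free, best.x)}
    best_params = base.replace(**kwargs)
    fixed_mask = {
        name: getattr(base, name) for name in PARAM_NAMES if name not in free
    }

    # profile curvature of log-likelihood along each free direction
    curvature: dict[str, float] = {}
    flat: list[str] = []
    f0 = float(best.fun)
    h = 0.05
    for i, name in enumerate(free):
        zp = best.x.copy()
        zp[i] += h
        zm = best.x.copy()
        zm[i] -= h
        d2 = (objective(zp) - 2.0 * f0 + objective(zm)) / h**2
        curvature[name] = float(d2)  # of -logL: positive = identified
        if d2 < _CURVATURE_FLAT:
            flat.append(name)

    return FitResult(
        best_params=best_params,
        log_likelihood=-f0,
        n_restarts=len(starts),
        converged=converged,
        restart_logliks=logliks,
        fixed_mask=fixed_mask,
        curvature=curvature,
        flat_directions=tuple(flat),
    )


def posterior_predictive(
    fit: FitResult,
    trials: list[TrialRecord],
    design: ExperimentDesign,
    rng,
    n_reps: int = 100,
    resolution: int = 61,
) -> pd.DataFrame:
    """Mean simulated reported confidence per trial under the fitted model.

    Re-simulates the report model ``n_reps`` times on the *same* trial
    sequence (internal posteriors are deterministic, so only report noise is
    resampled) and averages.
    """
    params = fit.best_params
    noise_rng = np.random.default_rng(_as_seedseq(rng))
    internal = internal_trajectory(trials, params, design, resolution)
    rows = []
    for trial, (p, revised) in zip(trials, internal):
        reps = [report_confidence(p, params, noise_rng) for _ in range(n_reps)]
        rev_mean = np.nan
        if revised is not None:
            rev_reps = [report_confidence(revised, params, noise_rng) for _ in range(n_reps)]
            rev_mean = float(np.mean(rev_reps))
        rows.append(
            {
                "participant_id": trial.participant_id,
                "block_index": trial.block_index,
                "trial_index": trial.trial_index,
                "confidence": float(np.mean(reps)),
                "revised_confidence": rev_mean,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """True-vs-fitted table and per-parameter summary of a recovery study."""

    table: pd.DataFrame  # one row per participant x parameter
    summary: pd.DataFrame  # correlation, bias, rmse per parameter
    fits: list[FitResult]


def recovery_study(
    n_participants: int,
    sample_params,
    design: ExperimentDesign,
    seed: int = 0,
    config: FitConfig = FitConfig(),
    base_params: ParticipantParams | None = None,
) -> RecoveryReport:
    """Simulate-then-refit validation of the fitting pipeline.

    ``sample_params(rng) -> ParticipantParams`` draws one true parameter
    vector (see :mod:`trustlearn.cohort` for the study-anchored laws).
    Fully reproducible from ``seed``.
    """
    from .behavior import simulate_participant

    master = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    rows = []
    fits = []
    for i in range(n_participants):
        truth = sample_params(param_rng)
        ss = np.random.SeedSequence(seed, spawn_key=(1, i))
        trials, responses = simulate_participant(
            design, truth, ss, participant_id=f"sim{i:03d}", resolution=config.resolution
        )
        fit = fit_participant(
            trials,
            responses,
            design,
            config=FitConfig(**{**config.__dict__, "seed": config.seed + 1000 + i}),
            base_params=base_params,
        )
        fits.append(fit)
        for name in PARAM_NAMES:
            rows.append(
                {
                    "participant_id": f"sim{i:03d}",
                    "parameter": name,
                    "true": getattr(truth, name),
                    "fitted": getattr(fit.best_params, name),
                    "free": name in config.free,
                }
            )
    table = pd.DataFrame(rows)
    summaries = []
    for name, grp in table.groupby("parameter", sort=True):
        t = grp["true"].to_numpy()
        f = grp["fitted"].to_numpy()
        if np.unique(t).size > 1 and np.unique(f).size > 1:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(stats.pearsonr(t, f)[0])
        else:
            r = np.nan
        summaries.append(
            {
                "parameter": name,
                "free": bool(grp["free"].iloc[0]),
                "correlation": r,
                "bias": float(np.mean(f - t)),
                "rmse": float(np.sqrt(np.mean((f - t) ** 2))),
                "median_fitted": float(np.median(f)),
            }
        )
    return RecoveryReport(table=table, summary=pd.DataFrame(summaries), fits=fits)
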