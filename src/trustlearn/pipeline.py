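"""File round-tripping, configuration, and the end-to-end replay.

All tables are tidy CSV with a fixed column schema; configs and summaries
are YAML.  ``run_replay`` chains cohort generation, per-participant fitting,
posterior prediction, and the psychometric analyses into one report
directory, and evaluates the qualitative fingerprint checks (sign structure
of the probe slopes/intercepts and the noisy-condition attenuation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import frame_to_responses
from .cohort import CohortBundle, CohortSpec, ParameterLaw, generate_cohort
from .fitting import FitConfig, fit_participant, posterior_predictive
from .psychometrics import (
    accuracy_curve,
    half_block_analysis,
    model_data_agreement,
    pooled_quarter_analysis,
    probe_analysis,
)
from .task import frame_to_trials

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "write_bundle",
    "read_bundle",
    "ReplayConfig",
    "run_replay",
]


class SchemaError(ValueError):
    """A table is missing or mistypes a required column."""


TRIAL_SCHEMA = {
    "participant_id": str,
    "block_index": int,
    "trial_index": int,
    "source_label": str,
    "state": str,
    "signal_X": int,
    "feedback_Y": object,
    "phase": str,
}

RESPONSE_SCHEMA = {
    "participant_id": str,
    "block_index": int,
    "trial_index": int,
    "confidence": float,
    "revised_confidence": float,  # NaN outside noisy-condition learning trials
    "binarized_choice": str,
}


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy table as CSV; floats keep full round-trip precision."""
    df.to_csv(path, index=False)


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    object_cols = [c for c, t in (schema or {}).items() if t is object]
    df = pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={c: object for c in object_cols},
    )
    if schema is not None:
        validate_schema(df, schema)
        for col, typ in schema.items():
            if typ is int:
                df[col] = df[col].astype(int)
            elif typ is float:
                df[col] = df[col].astype(float)
            elif typ is str:
                df[col] = df[col].astype(str)
            elif typ is object:
                # mixed column: numeric (council counts, NaN on probes) or
                # categorical strings with None
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    df[col] = df[col].where(pd.notna(df[col]), None)
    return df


def validate_schema(df: pd.DataFrame, schema: dict) -> None:
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"unexpected columns {extra!r}")


def _spec_to_config(spec: CohortSpec) -> dict:
    return {
        "condition": spec.condition,
        "n_participants": spec.n_participants,
        "master_seed": spec.master_seed,
        "resolution": spec.resolution,
        "parameter_distributions": {
            name: dataclasses.asdict(law)
            for name, law in spec.parameter_distributions.items()
        },
    }


def _config_to_spec(cfg: dict) -> CohortSpec:
    laws = {
        name: ParameterLaw(**law)
        for name, law in cfg.get("parameter_distributions", {}).items()
    }
    return CohortSpec(
        condition=cfg["condition"],
        n_participants=cfg.get("n_participants"),
        parameter_distributions=laws,
        master_seed=cfg.get("master_seed", 0),
        resolution=cfg.get("resolution", 61),
    )


def write_bundle(bundle: CohortBundle, directory) -> Path:
    """Write a cohort bundle as a directory of tables plus its config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_table(bundle.trials, directory / "trials.csv")
    write_table(bundle.responses, directory / "responses.csv")
    write_table(bundle.params, directory / "true_params.csv")
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(_spec_to_config(bundle.spec), fh, sort_keys=False)
    return directory


def read_bundle(directory) -> CohortBundle:
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    spec = _config_to_spec(cfg)
    trials = read_table(directory / "trials.csv", TRIAL_SCHEMA)
    responses = read_table(directory / "responses.csv", RESPONSE_SCHEMA)
    params = read_table(directory / "true_params.csv")
    return CohortBundle(spec=spec, trials=trials, responses=responses, params=params)


# ---------------------------------------------------------------------------
# end-to-end replay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplayConfig:
    condition: str = "full_feedback"
    n_participants: int | None = None
    seed: int = 0
    resolution: int = 61
    fit: bool = True
    n_restarts: int = 4
    n_predictive_reps: int = 50
    fit_free: tuple[str, ...] = (
        "prior_mean",
        "prior_strength",
        "updating_ratio",
        "forget_rate",
        "response_noise",
    )

    @classmethod
    def from_yaml(cls, path) -> "ReplayConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "fit_free" in cfg:
            cfg["fit_free"] = tuple(cfg["fit_free"])
        return cls(**cfg)


def _fingerprint(probe_fits: pd.DataFrame, condition: str) -> dict:
    """Sign-structure checks on mean probe slopes/intercepts per source."""
    means = probe_fits.groupby("source_label")[["slope", "intercept"]].mean()
    slopes = means["slope"]
    intercepts = means["intercept"]
    checks = {
        "slope_opposite_negative": bool(slopes["opposite"] < 0),
        "slope_helpful_positive": bool(slopes["helpful"] > 0),
        "slope_blue_biased_positive": bool(slopes["blue_biased"] > 0),
        "slope_random_near_zero": bool(
            abs(slopes["random"]) < min(slopes["helpful"], -slopes["opposite"])
        ),
        "slope_ordering": bool(
            slopes["opposite"]
            < slopes["random"]
            < slopes["blue_biased"] + 1e-12
        )
        and bool(slopes["blue_biased"] <= slopes["helpful"] + 0.25),
        "intercept_most_negative_blue_biased": bool(
            intercepts["blue_biased"] == intercepts.min()
        ),
    }
    checks["mean_slopes"] = {k: float(v) for k, v in slopes.items()}
    checks["mean_intercepts"] = {k: float(v) for k, v in intercepts.items()}
    checks["condition"] = condition
    return checks


def run_replay(config: ReplayConfig, out_dir) -> Path:
    """Generate a cohort, fit it, analyze data and model, write a report.

    Returns the report directory.  Raises on any stage failure rather than
    producing a partial report silently.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(
        condition=config.condition,
        n_participants=config.n_participants,
        master_seed=config.seed,
        resolution=config.resolution,
    )
    bundle = generate_cohort(spec)
    write_bundle(bundle, out / "cohort")
    design = spec.design()

    trials_df, responses_df = bundle.trials, bundle.responses
    probe_fits = probe_analysis(trials_df, responses_df)
    quarter_fits = pooled_quarter_analysis(trials_df, responses_df)
    half_fits = half_block_analysis(trials_df, responses_df)
    accuracy = accuracy_curve(trials_df, responses_df)
    write_table(probe_fits, out / "probe_fits.csv")
    write_table(quarter_fits, out / "quarter_fits.csv")
    write_table(half_fits, out / "half_fits.csv")
    write_table(accuracy, out / "accuracy.csv")

    summary: dict = {
        "version": __version__,
        "config": {**dataclasses.asdict(config), "fit_free": list(config.fit_free)},
        "fingerprint": _fingerprint(probe_fits, config.condition),
    }

    if config.fit:
        fit_rows, pred_frames = [], []
        for i, pid in enumerate(bundle.participant_ids()):
            p_trials = frame_to_trials(
                trials_df[trials_df["participant_id"] == pid]
            )
            p_responses = frame_to_responses(
                responses_df[responses_df["participant_id"] == pid]
            )
            fit = fit_participant(
                p_trials,
                p_responses,
                design,
                config=FitConfig(
                    free=config.fit_free,
                    n_restarts=config.n_restarts,
                    seed=config.seed + 7000 + i,
                    resolution=config.resolution,
                ),
            )
            fit_rows.append(
                {
                    "participant_id": pid,
                    "log_likelihood": fit.log_likelihood,
                    **fit.best_params.as_dict(),
                }
            )
            pred = posterior_predictive(
                fit,
                p_trials,
                design,
                np.random.SeedSequence(config.seed, spawn_key=(9, i)),
                n_reps=config.n_predictive_reps,
                resolution=config.resolution,
            )
            pred_frames.append(pred)
        fits_df = pd.DataFrame(fit_rows)
        write_table(fits_df, out / "participant_fits.csv")
        pred_df = pd.concat(pred_frames, ignore_index=True)
        pred_df["binarized_choice"] = np.where(
            pred_df["confidence"] > 0.5, "blue", "green"
        )
        write_table(pred_df, out / "posterior_predictive.csv")

        model_probe = probe_analysis(trials_df, pred_df)
        write_table(model_probe, out / "model_probe_fits.csv")
        summary["model_data_agreement"] = model_data_agreement(probe_fits, model_probe)

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return out
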