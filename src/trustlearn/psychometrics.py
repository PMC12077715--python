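"""Psychometric read-outs of trial-level confidence data.

The central behavioral summary is a logistic regression of confidence on the
centered signal count ``X - 2.5``:

    logit E[confidence] = intercept + slope * (X - 2.5)

The slope measures how strongly (and in which direction) the responder
integrates the source's evidence; the intercept measures response bias at an
ambivalent signal.  For a responder who knows a symmetric source with
reliability q exactly, the slope is ``2 * ln(q / (1 - q))`` per endorsement
(``2 ln 3 ≈ 2.197`` at q = 0.75) and the intercept is 0; a blue-biased
source shifts the intercept negative.

Continuous confidences are treated as fractional binomial responses and fit
by minimizing the binomial deviance with Newton/IRLS iterations; a
binarized variant is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .task import BLUE, LEARNING, PROBE

__all__ = [
    "PsychometricFit",
    "DegenerateSegmentError",
    "fit_psychometric",
    "probe_analysis",
    "pooled_quarter_analysis",
    "half_block_analysis",
    "accuracy_curve",
    "model_data_agreement",
]

CENTER = 2.5  # subtracted from the signal count so no-bias => intercept 0
SLOPE_CAP = 25.0
_CLIP = 1e-3


class DegenerateSegmentError(ValueError):
    """Raised when a segment has fewer than two distinct signal values."""


@dataclass(frozen=True)
class PsychometricFit:
    """Slope/intercept of the logistic response curve for one segment."""

    source_label: str
    segment: str
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    n_points: int
    separated: bool = False


def _deviance_fit(x: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Newton/IRLS minimization of the fractional binomial deviance.

    Returns (intercept, slope, se_intercept, se_slope, separated).
    """
    X = np.column_stack([np.ones_like(x), x])

    def deviance(b):
        mu = special.expit(X @ b)
        mu = np.clip(mu, 1e-15, 1.0 - 1e-15)
        return -2.0 * float(y @ np.log(mu) + (1.0 - y) @ np.log1p(-mu))

    beta = np.zeros(2)
    dev = deviance(beta)
    separated = False
    for _ in range(max_iter):
        mu = special.expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # damped Newton: halve the step until the deviance does not increase
        scale = 1.0
        for _halving in range(30):
            cand = beta + scale * step
            cand_dev = deviance(cand)
            if cand_dev <= dev + 1e-14:
                break
            scale *= 0.5
        beta, dev = cand, cand_dev
        if np.abs(beta[1]) > SLOPE_CAP or np.abs(beta[0]) > SLOPE_CAP:
            separated = True
            beta = np.clip(beta, -SLOPE_CAP, SLOPE_CAP)
            break
        if np.max(np.abs(scale * step)) < tol:
            break
    eta = X @ beta
    mu = special.expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return float(beta[0]), float(beta[1]), float(se[0]), float(se[1]), separated


def fit_psychometric(
    signals,
    confidences,
    *,
    source_label: str = "",
    segment: str = "whole",
    binarize: bool = False,
) -> PsychometricFit:
    """Fit logit E[c] = intercept + slope * (X - 2.5) to one segment.

    ``binarize`` thresholds the confidences at 0.5 before fitting instead of
    using them as fractional responses.
    """
    x = np.asarray(signals, dtype=float)
    c = np.asarray(confidences, dtype=float)
    if x.shape != c.shape or x.ndim != 1:
        raise ValueError("signals and confidences must be equal-length 1-d arrays")
    if np.unique(x).size < 2:
        raise DegenerateSegmentError(
            "psychometric fit needs at least 2 distinct signal values"
        )
    if binarize:
        y = (c > 0.5).astype(float) + 0.5 * (c == 0.5)
    else:
        y = np.clip(c, _CLIP, 1.0 - _CLIP)
    intercept, slope, se_i, se_s, separated = _deviance_fit(x - CENTER, y)
    return PsychometricFit(
        source_label=source_label,
        segment=segment,
        slope=slope,
        intercept=intercept,
        se_slope=se_s,
        se_intercept=se_i,
        n_points=x.size,
        separated=separated,
    )


# ---------------------------------------------------------------------------
# segment analyses on tidy trial/response tables
# ---------------------------------------------------------------------------

def _merged(trials: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
    keys = ["participant_id", "block_index", "trial_index"]
    df = trials.merge(responses, on=keys, validate="one_to_one")
    if len(df) != len(trials):
        raise ValueError("trials and responses tables do not align one-to-one")
    return df


def _fit_or_flag(group: pd.DataFrame, label: str, segment: str, binarize: bool):
    try:
        return fit_psychometric(
            group["signal_X"].to_numpy(),
            group["confidence"].to_numpy(),
            source_label=label,
            segment=segment,
            binarize=binarize,
        )
    except DegenerateSegmentError:
        return PsychometricFit(label, segment, np.nan, np.nan, np.nan, np.nan,
                               len(group), separated=False)


def probe_analysis(
    trials: pd.DataFrame, responses: pd.DataFrame, *, binarize: bool = False
) -> pd.DataFrame:
    """Per-participant, per-source fits to the probe trials only."""
    df = _merged(trials, responses)
    df = df[df["phase"] == PROBE]
    rows = []
    for (pid, label), grp in df.groupby(["participant_id", "source_label"], sort=True):
        fit = _fit_or_flag(grp, label, "probe", binarize)
        rows.append({"participant_id": pid, **fit.__dict__})
    return pd.DataFrame(rows)


def _quarter_of(trial_index: np.ndarray, n_learning: int = 28) -> np.ndarray:
    """Quarter label 1..4 for 0-based learning-trial indices (7 trials each)."""
    q = n_learning // 4
    return (trial_index // q + 1).astype(int)


def pooled_quarter_analysis(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    n_learning: int = 28,
    binarize: bool = False,
) -> pd.DataFrame:
    """Fits per source × block quarter, pooled across participants."""
    df = _merged(trials, responses)
    df = df[df["phase"] == LEARNING].copy()
    df["quarter"] = _quarter_of(df["trial_index"].to_numpy(), n_learning)
    rows = []
    for (label, quarter), grp in df.groupby(["source_label", "quarter"], sort=True):
        fit = _fit_or_flag(grp, label, f"quarter-{quarter}", binarize)
        rows.append({"quarter": int(quarter), **fit.__dict__})
    return pd.DataFrame(rows)


def half_block_analysis(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    n_learning: int = 28,
    binarize: bool = False,
) -> pd.DataFrame:
    """Per-participant fits to the first and second halves of each block."""
    df = _merged(trials, responses)
    df = df[df["phase"] == LEARNING].copy()
    df["half"] = (df["trial_index"] >= n_learning // 2).astype(int) + 1
    rows = []
    for (pid, label, half), grp in df.groupby(
        ["participant_id", "source_label", "half"], sort=True
    ):
        fit = _fit_or_flag(grp, label, f"half-{half}", binarize)
        rows.append({"participant_id": pid, "half": int(half), **fit.__dict__})
    return pd.DataFrame(rows)


def accuracy_curve(
    trials: pd.DataFrame, responses: pd.DataFrame, *, n_learning: int = 28
) -> pd.DataFrame:
    """Mean binarized accuracy per source × quarter on learning trials.

    A confidence above 0.5 counts as a blue choice, below 0.5 as green, and
    exactly 0.5 scores half a point.
    """
    df = _merged(trials, responses)
    df = df[df["phase"] == LEARNING].copy()
    df["quarter"] = _quarter_of(df["trial_index"].to_numpy(), n_learning)
    conf = df["confidence"].to_numpy()
    blue = (df["state"] == BLUE).to_numpy()
    correct = np.where(
        conf == 0.5, 0.5, np.where((conf > 0.5) == blue, 1.0, 0.0)
    )
    df["correct"] = correct
    out = (
        df.groupby(["source_label", "quarter"], sort=True)["correct"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "accuracy", "size": "n_trials"})
    )
    return out


def model_data_agreement(data_fits: pd.DataFrame, model_fits: pd.DataFrame) -> dict:
    """Pearson correlation of slopes and intercepts between paired fit tables.

    Tables are paired on participant × source (and segment/half where
    present).  A constant column on either side leaves the correlation
    undefined (NaN) with a flag.
    """
    keys = [
        k
        for k in ("participant_id", "source_label", "segment", "half", "quarter")
        if k in data_fits.columns and k in model_fits.columns
    ]
    merged = data_fits.merge(model_fits, on=keys, suffixes=("_data", "_model"))
    out: dict = {"n": len(merged)}
    for quantity in ("slope", "intercept"):
        a = merged[f"{quantity}_data"].to_numpy(dtype=float)
        b = merged[f"{quantity}_model"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            out[f"{quantity}_r"] = np.nan
            out[f"{quantity}_undefined"] = True
        else:
            r, _ = stats.pearsonr(a, b)
            out[f"{quantity}_r"] = float(r)
            out[f"{quantity}_undefined"] = False
    return out
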