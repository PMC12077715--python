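"""Psychometric fits and the derived behavioral read-outs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from trustlearn.behavior import ParticipantParams, simulate_participant, responses_to_frame
from trustlearn.psychometrics import (
    DegenerateSegmentError,
    accuracy_curve,
    fit_psychometric,
    half_block_analysis,
    model_data_agreement,
    pooled_quarter_analysis,
    probe_analysis,
)
from trustlearn.task import ExperimentDesign, trials_to_frame

SLOPE_75 = 2 * math.log(3)  # known-source slope at q = 0.75


def logistic_confidences(x, slope, intercept):
    return special.expit(intercept + slope * (x - 2.5))


class TestFitPsychometric:
    @pytest.mark.parametrize(
        "slope,intercept",
        [(SLOPE_75, 0.0), (-SLOPE_75, 0.0), (1.3, -0.8), (0.0, 0.4), (2.2, 0.5)],
    )
    def test_self_inversion_on_noiseless_data(self, slope, intercept):
        x = np.arange(6, dtype=float)
        c = logistic_confidences(x, slope, intercept)
        fit = fit_psychometric(x, c)
        assert fit.slope == pytest.approx(slope, abs=1e-6)
        assert fit.intercept == pytest.approx(intercept, abs=1e-6)

    def test_indifferent_responses_give_zero(self):
        fit = fit_psychometric(np.arange(6), np.full(6, 0.5))
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_mirror_symmetries(self):
        """Reflecting the signal negates the slope; relabeling the response
        colors (c -> 1-c) negates both coefficients."""
        rng = np.random.default_rng(0)
        x = np.tile(np.arange(6), 4).astype(float)
        c = np.clip(logistic_confidences(x, 1.1, -0.4)
                    + rng.normal(0, 0.05, x.size), 0.01, 0.99)
        f = fit_psychometric(x, c)
        sig = fit_psychometric(5 - x, c)
        assert sig.slope == pytest.approx(-f.slope, abs=1e-8)
        assert sig.intercept == pytest.approx(f.intercept, abs=1e-8)
        col = fit_psychometric(x, 1 - c)
        assert col.slope == pytest.approx(-f.slope, abs=1e-8)
        assert col.intercept == pytest.approx(-f.intercept, abs=1e-8)

    def test_single_signal_value_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            fit_psychometric(np.full(6, 3.0), np.linspace(0.2, 0.8, 6))

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = np.tile(np.arange(6), 10).astype(float)
        c = np.clip(
            logistic_confidences(x, 0.9, -0.3) + rng.normal(0, 0.08, x.size),
            0.001, 0.999,
        )
        ours = fit_psychometric(x, c)
        X = sm.add_constant(x - 2.5)
        glm = sm.GLM(c, X, family=sm.families.Binomial()).fit()
        assert ours.intercept == pytest.approx(glm.params[0], abs=1e-6)
        assert ours.slope == pytest.approx(glm.params[1], abs=1e-6)

    def test_separated_data_capped_and_flagged(self):
        x = np.array([0.0, 1.0, 4.0, 5.0])
        c = np.array([0.0, 0.0, 1.0, 1.0])  # clipped internally to 0.001/0.999
        fit = fit_psychometric(x, c)
        assert abs(fit.slope) <= 25.0
        if fit.separated:
            assert abs(fit.slope) == 25.0


@pytest.fixture(scope="module")
def ideal_cohort_frames():
    """Small cohort of near-ideal learners under full feedback."""
    design = ExperimentDesign.full_feedback()
    params = ParticipantParams(prior_mean=0.55, prior_strength=2.0,
                               response_noise=0.05)
    all_t, all_r = [], []
    for i in range(20):
        t, r = simulate_participant(design, params, np.random.SeedSequence(50, spawn_key=(i,)),
                                    participant_id=f"i{i:02d}")
        all_t.extend(t)
        all_r.extend(r)
    return trials_to_frame(all_t), responses_to_frame(all_r)


class TestProbeAnalysis:
    def test_converged_helpful_and_biased_signatures(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = probe_analysis(trials, responses)
        means = fits.groupby("source_label")[["slope", "intercept"]].mean()
        assert means.loc["helpful", "slope"] == pytest.approx(SLOPE_75, abs=0.4)
        assert abs(means.loc["helpful", "intercept"]) < 0.3
        assert means.loc["blue_biased", "slope"] > 0
        assert means.loc["blue_biased", "intercept"] < 0
        assert means.loc["opposite", "slope"] < 0

    def test_one_fit_per_participant_per_source(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = probe_analysis(trials, responses)
        assert len(fits) == 20 * 4
        assert (fits["n_points"] == 6).all()


class TestTrajectories:
    def test_quarter_partition(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = pooled_quarter_analysis(trials, responses)
        assert sorted(fits["quarter"].unique()) == [1, 2, 3, 4]
        assert (fits.groupby("source_label").size() == 4).all()
        # 20 participants x 7 trials per quarter
        assert (fits["n_points"] == 140).all()

    def test_opposite_slope_declines_across_quarters(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = pooled_quarter_analysis(trials, responses)
        opp = fits[fits["source_label"] == "opposite"].set_index("quarter")["slope"]
        assert opp[4] < opp[1]

    def test_blue_biased_intercept_declines(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = pooled_quarter_analysis(trials, responses)
        bb = fits[fits["source_label"] == "blue_biased"].set_index("quarter")["intercept"]
        assert bb[4] < bb[1]

    def test_half_block_split_and_learning(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = half_block_analysis(trials, responses)
        assert set(fits["half"]) == {1, 2}
        assert (fits["n_points"] == 14).all()
        opp = fits[fits["source_label"] == "opposite"]
        by_half = opp.groupby("half")["slope"].mean()
        assert by_half[2] < by_half[1]

    def test_degenerate_half_flagged_not_fabricated(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["p"] * 4,
                "block_index": [0] * 4,
                "trial_index": [0, 1, 2, 3],
                "source_label": ["helpful"] * 4,
                "state": ["blue"] * 4,
                "signal_X": [3, 3, 3, 3],
                "feedback_Y": ["blue"] * 4,
                "phase": ["learning"] * 4,
            }
        )
        responses = pd.DataFrame(
            {
                "participant_id": ["p"] * 4,
                "block_index": [0] * 4,
                "trial_index": [0, 1, 2, 3],
                "confidence": [0.6, 0.7, 0.6, 0.7],
                "revised_confidence": [None] * 4,
                "binarized_choice": ["blue"] * 4,
            }
        )
        fits = half_block_analysis(trials, responses, n_learning=4)
        assert fits["slope"].isna().all()


class TestAccuracy:
    def test_indifferent_responder_scores_half(self, ideal_cohort_frames):
        trials, _ = ideal_cohort_frames
        flat = pd.DataFrame(
            {
                "participant_id": trials["participant_id"],
                "block_index": trials["block_index"],
                "trial_index": trials["trial_index"],
                "confidence": 0.5,
                "revised_confidence": None,
                "binarized_choice": "blue",
            }
        )
        acc = accuracy_curve(trials, flat)
        assert np.allclose(acc["accuracy"], 0.5)

    def test_learning_curve_rises_for_helpful(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        acc = accuracy_curve(trials, responses)
        helpful = acc[acc["source_label"] == "helpful"].set_index("quarter")["accuracy"]
        random_src = acc[acc["source_label"] == "random"].set_index("quarter")["accuracy"]
        assert helpful[4] > 0.8
        assert abs(random_src.mean() - 0.5) < 0.1


class TestAgreement:
    def test_perfect_agreement(self, ideal_cohort_frames):
        trials, responses = ideal_cohort_frames
        fits = probe_analysis(trials, responses)
        out = model_data_agreement(fits, fits)
        assert out["slope_r"] == pytest.approx(1.0)
        assert out["intercept_r"] == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_correlation(self):
        rng = np.random.default_rng(0)
        n = 400
        base = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "source_label": ["helpful"] * n,
                "segment": ["probe"] * n,
                "slope": rng.normal(2, 1, n),
                "intercept": rng.normal(0, 1, n),
            }
        )
        shuffled = base.copy()
        shuffled[["slope", "intercept"]] = (
            base[["slope", "intercept"]].sample(frac=1, random_state=1).to_numpy()
        )
        out = model_data_agreement(base, shuffled)
        assert abs(out["slope_r"]) < 0.15
        assert out["n"] == n

    def test_constant_fits_flagged_undefined(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "source_label": ["helpful"] * 3,
                "slope": [1.0, 2.0, 3.0],
                "intercept": [0.1, 0.0, -0.1],
            }
        )
        const = df.copy()
        const["slope"] = 1.0
        const["intercept"] = 0.0
        out = model_data_agreement(df, const)
        assert math.isnan(out["slope_r"]) and out["slope_undefined"]
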