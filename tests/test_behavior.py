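"""Parameterized human-like learner: priors, biased updates, report model."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from trustlearn.behavior import (
    ParticipantParams,
    apply_forgetting,
    asymmetric_update,
    internal_trajectory,
    make_prior,
    report_confidence,
    response_loglik,
    simulate_participant,
)
from trustlearn.ideal import (
    BeliefGrid,
    ConjugateBelief,
    run_optimal_agent,
    state_posterior,
)
from trustlearn.task import BLUE, GREEN, generate_experiment


class TestPrior:
    def test_flat_prior(self):
        p = make_prior(ParticipantParams(prior_mean=0.5, prior_strength=2.0))
        assert (p.alpha_b, p.beta_b, p.alpha_g, p.beta_g) == (1, 1, 1, 1)

    def test_moment_matching(self):
        p = make_prior(ParticipantParams(prior_mean=0.6, prior_strength=10.0))
        assert (p.alpha_b, p.beta_b) == (pytest.approx(6.0), pytest.approx(4.0))
        assert p.mean_g == pytest.approx(0.6)

    def test_grid_prior_mean(self):
        p = make_prior(
            ParticipantParams(prior_mean=0.6, prior_strength=10.0), "grid", 201
        )
        assert p.mean_b == pytest.approx(0.6, abs=1e-3)

    @pytest.mark.parametrize(
        "bad",
        [
            {"prior_mean": 0.0},
            {"prior_strength": -1.0},
            {"updating_ratio": 0.0},
            {"forget_rate": 1.5},
            {"response_noise": 0.0},
            {"lapse_rate": -0.1},
            {"council_weight": 1.2},
        ],
    )
    def test_bounds_enforced(self, bad):
        with pytest.raises(ValueError):
            ParticipantParams(**bad)


class TestAsymmetricUpdate:
    def test_neutral_equals_ideal(self):
        from trustlearn.ideal import update_full

        b = ConjugateBelief(2.0, 3.0, 1.0, 1.0)
        neutral = ParticipantParams()
        assert asymmetric_update(b, 4, BLUE, neutral) == update_full(b, 4, BLUE, 5)

    def test_eta_scales_confirming_counts(self):
        params = ParticipantParams(updating_ratio=2.0)
        up = asymmetric_update(ConjugateBelief.flat(), 4, BLUE, params)
        assert (up.alpha_b, up.beta_b) == (9.0, 2.0)

    def test_green_state_scales_green_counts(self):
        params = ParticipantParams(updating_ratio=2.0)
        up = asymmetric_update(ConjugateBelief.flat(), 1, GREEN, params)
        assert (up.alpha_g, up.beta_g) == (9.0, 2.0)

    def test_vanishing_eta_suppresses_hopeful_learning(self):
        # as eta -> 0 confirming evidence stops counting: the belief can only
        # drift down under a stream of strongly confirming signals
        params = ParticipantParams(updating_ratio=1e-4)
        b = ConjugateBelief.flat()
        means = [b.mean_b]
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = int(rng.binomial(5, 0.9))  # strongly confirming evidence
            b = asymmetric_update(b, x, BLUE, params)
            means.append(b.mean_b)
        # non-increasing up to the vanishing eta contribution
        assert all(m2 <= m1 + 5 * 1e-4 for m1, m2 in zip(means, means[1:]))
        assert means[-1] < means[0]

    def test_grid_and_conjugate_asymmetry_agree(self):
        params = ParticipantParams(updating_ratio=1.7)
        cb = asymmetric_update(ConjugateBelief.flat(), 4, BLUE, params)
        grid = asymmetric_update(BeliefGrid.flat(401), 4, BLUE, params)
        assert grid.mean_b == pytest.approx(cb.mean_b, abs=1e-3)


class TestForgetting:
    def test_zero_rate_identity(self):
        b = ConjugateBelief(5, 2, 3, 4)
        assert apply_forgetting(b, ConjugateBelief.flat(), ParticipantParams()) is b

    def test_full_forgetting_returns_prior(self):
        prior = ConjugateBelief(1.2, 0.8, 1.2, 0.8)
        b = ConjugateBelief(9, 2, 3, 4)
        out = apply_forgetting(b, prior, ParticipantParams(forget_rate=1.0))
        assert out.alpha_b == pytest.approx(prior.alpha_b)
        assert out.beta_g == pytest.approx(prior.beta_g)

    def test_steady_state_between_prior_and_truth(self):
        # the decayed recursion equilibrates, in expectation, strictly
        # between the prior mean and the data-generating reliability
        params = ParticipantParams(forget_rate=0.1)
        prior = make_prior(params)
        rng = np.random.default_rng(4)
        finals = []
        for _ in range(200):
            b = prior
            for _ in range(50):
                state = BLUE if rng.random() < 0.5 else GREEN
                x = int(rng.binomial(5, 0.75 if state == BLUE else 0.25))
                b = asymmetric_update(b, x, state, params)
                b = apply_forgetting(b, prior, params)
            finals.append(b.mean_b)
        mean_final = float(np.mean(finals))
        assert 0.55 < mean_final < 0.745


class TestReportModel:
    def test_noiseless_limit(self):
        params = ParticipantParams(response_noise=1e-12)
        rng = np.random.default_rng(0)
        assert report_confidence(0.73, params, rng) == pytest.approx(0.73, abs=1e-9)

    def test_compression_shrinks_logit(self):
        params = ParticipantParams(response_compression=0.4, response_noise=1e-12)
        rng = np.random.default_rng(0)
        r = report_confidence(0.9, params, rng)
        assert 0.5 < r < 0.9

    def test_reports_respect_slider_clip(self):
        params = ParticipantParams(response_noise=3.0, lapse_rate=0.2)
        rng = np.random.default_rng(1)
        reports = [report_confidence(0.99, params, rng) for _ in range(500)]
        assert all(0.001 <= r <= 0.999 for r in reports)

    def test_mean_report_matches_quadrature(self):
        """Monte-Carlo mean of reports equals the logit-normal mean."""
        sigma, p = 0.5, 0.8
        mu = special.logit(p)
        exact, _ = integrate.quad(
            lambda z: special.expit(z) * stats.norm.pdf(z, mu, sigma), -20, 20
        )
        params = ParticipantParams(response_noise=sigma)
        rng = np.random.default_rng(2)
        draws = np.array([report_confidence(p, params, rng) for _ in range(10_000)])
        assert abs(draws.mean() - exact) < 3 * draws.std() / math.sqrt(draws.size)


class TestReductionToIdeal:
    def test_full_condition_internal_posteriors_match(self, full_design):
        trials = generate_experiment(full_design, "p", 5)
        internal = internal_trajectory(trials, ParticipantParams.ideal(), full_design)
        # optimal agent per block with the same flat prior
        blocks = {}
        for t in trials:
            blocks.setdefault(t.block_index, []).append(t)
        ideal_conf = []
        for k in sorted(blocks):
            ideal_conf.extend(
                r["confidence"] for r in run_optimal_agent(blocks[k], full_design)
            )
        got = [p for p, _ in internal]
        np.testing.assert_allclose(got, ideal_conf, atol=1e-12)

    def test_noisy_condition_reduction(self, noisy_design):
        trials = generate_experiment(noisy_design, "p", 6)[:34]
        internal = internal_trajectory(
            trials, ParticipantParams.ideal(), noisy_design, resolution=31
        )
        ideal = run_optimal_agent(trials, noisy_design, resolution=31)
        np.testing.assert_allclose(
            [p for p, _ in internal], [r["confidence"] for r in ideal], atol=1e-10
        )
        np.testing.assert_allclose(
            [r2 for _, r2 in internal if r2 is not None],
            [r["revised_confidence"] for r in ideal if r["revised_confidence"] is not None],
            atol=1e-10,
        )

    def test_prior_dominance(self, full_design):
        """A very strong trusting prior pins early responses at the known-source curve."""
        params = ParticipantParams(prior_mean=0.7, prior_strength=5e4)
        trials = generate_experiment(full_design, "p", 7)
        internal = internal_trajectory(trials, params, full_design)
        known = BeliefGrid.point_mass(0.7, 0.7)
        first = trials[0]
        expected = state_posterior(known, first.signal_X, 5)
        assert internal[0][0] == pytest.approx(expected, abs=1e-3)


class TestSimulateAndLoglik:
    def test_noisy_simulation_has_two_ratings_on_learning_trials(self, noisy_design):
        params = ParticipantParams()
        trials, responses = simulate_participant(noisy_design, params, 3, resolution=31)
        for t, r in zip(trials, responses):
            if t.phase == "learning":
                assert r.revised_confidence is not None
            else:
                assert r.revised_confidence is None

    def test_lapse_only_model_has_zero_loglik(self, full_design):
        params = ParticipantParams(lapse_rate=1.0)
        trials, responses = simulate_participant(full_design, params, 8)
        assert response_loglik(params, trials, responses, full_design) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_loglik_deterministic(self, full_design):
        params = ParticipantParams(prior_mean=0.6)
        trials, responses = simulate_participant(full_design, params, 9)
        a = response_loglik(params, trials, responses, full_design)
        b = response_loglik(params, trials, responses, full_design)
        assert a == b

    def test_misaligned_logs_rejected(self, full_design):
        params = ParticipantParams()
        trials, responses = simulate_participant(full_design, params, 10)
        with pytest.raises(ValueError):
            response_loglik(params, trials, responses[:-1], full_design)
        with pytest.raises(ValueError):
            response_loglik(params, trials, list(reversed(responses)), full_design)

    def test_likelihood_dominance_at_truth(self, full_design):
        """Generating parameters beat a perturbed vector on average."""
        truth = ParticipantParams(prior_mean=0.6, prior_strength=4.0,
                                  response_noise=0.5)
        perturbed = truth.replace(prior_mean=0.4, updating_ratio=2.0)
        diffs = []
        for i in range(100):
            trials, responses = simulate_participant(full_design, truth, 100 + i)
            diffs.append(
                response_loglik(truth, trials, responses, full_design)
                - response_loglik(perturbed, trials, responses, full_design)
            )
        assert np.mean(diffs) > 0
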