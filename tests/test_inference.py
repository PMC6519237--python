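"""Belief updating over another agent's harm aversion: oracle and learners."""

import numpy as np
import pytest
from scipy.special import expit

from moralcog import inference as inf
from moralcog import synthetic
from moralcog.inference import (
    RatingMap,
    batch_grid_posterior,
    compare_models,
    fit_inference,
    fit_rating_map,
    gaussian_update,
    grid_filter_update,
    initial_gaussian_belief,
    initial_grid_belief,
    predict_from_belief,
    probe_prediction,
    run_learner,
    rw_update,
)
from moralcog.types import (
    BeliefState,
    DecisionTrial,
    InferenceParams,
    PredictionRecord,
)
from .conftest import make_session


class TestPredictFromBelief:
    def test_indifference_gives_half(self):
        mu = 0.4  # indifference when dm/ds = mu/(1-mu) = 2/3
        t = DecisionTrial(dm=2, ds=3)
        assert predict_from_belief(mu, t, 5.0) == pytest.approx(0.5)

    def test_zero_consistency_gives_half(self):
        assert predict_from_belief(0.9, DecisionTrial(dm=10, ds=1), 0.0) == 0.5

    def test_closed_form(self):
        # mu=0.5, dm=2, ds=1 -> V=0.5; beta=2 -> logistic(1)
        p = predict_from_belief(0.5, DecisionTrial(dm=2, ds=1), 2.0)
        assert p == pytest.approx(expit(1.0), abs=1e-12)

    def test_out_of_range_mu_rejected(self):
        with pytest.raises(ValueError):
            predict_from_belief(1.2, DecisionTrial(dm=1, ds=1), 1.0)


class TestGridFilter:
    def test_two_point_hand_bayes(self):
        # uniform prior on {0.3, 0.7}; one harmful choice on (dm=10, ds=2, beta=1)
        grid = np.array([0.3, 0.7])
        belief = BeliefState(
            mu=0.5, sigma=0.04, trial_index=0,
            grid=tuple(grid), grid_density=(0.5, 0.5),
        )
        params = InferenceParams(omega=-50.0, beta_pred=1.0, beta_agent=1.0)
        t = DecisionTrial(dm=10, ds=2)
        post = grid_filter_update(belief, t, True, params)
        p03 = expit(0.7 * 10 - 0.3 * 2)
        p07 = expit(0.3 * 10 - 0.7 * 2)
        expected = np.array([p03, p07]) / (p03 + p07)
        np.testing.assert_allclose(post.grid_density, expected, atol=1e-12)

    def test_sequential_equals_batch_without_diffusion(self):
        agent, session = make_session("bad", 30, seed=3)
        params = InferenceParams(omega=-50.0, beta_pred=5.0, beta_agent=agent.beta_agent)
        belief = initial_grid_belief(params)
        for rec in session:
            belief = grid_filter_update(belief, rec.trial, rec.agent_choice, params)
        batch = batch_grid_posterior(
            [r.trial for r in session], [r.agent_choice for r in session], params
        )
        diff = np.abs(np.array(belief.grid_density) - np.array(batch.grid_density))
        assert diff.max() < 1e-10

    def test_density_stays_normalized(self):
        agent, session = make_session("good", 40, seed=1)
        params = InferenceParams(omega=-3.0, beta_pred=3.0)
        belief = initial_grid_belief(params)
        for rec in session:
            belief = grid_filter_update(belief, rec.trial, rec.agent_choice, params)
            total = np.sum(belief.grid_density)
            assert abs(total - 1.0) < 1e-10
            assert 0.0 <= belief.mu <= 1.0
            assert belief.sigma <= 1.0 / 12.0 + 1e-6

    def test_flat_likelihood_returns_diffused_prior(self):
        # dm == ds * k/(1-k) for all grid points is impossible; instead use
        # beta_agent = 0, which makes every choice uninformative
        params = InferenceParams(omega=-50.0, beta_pred=1.0, beta_agent=0.0)
        belief = initial_grid_belief(params)
        post = grid_filter_update(belief, DecisionTrial(dm=3, ds=2), True, params)
        np.testing.assert_allclose(post.grid_density, belief.grid_density, atol=1e-12)

    def test_requires_grid_density(self):
        b = BeliefState(mu=0.5, sigma=0.1, trial_index=0)
        with pytest.raises(ValueError):
            grid_filter_update(b, DecisionTrial(dm=1, ds=1), True, InferenceParams())


class TestGaussianLearner:
    def test_update_moves_toward_observed_choice(self):
        params = InferenceParams(omega=-4.0, beta_pred=3.0)
        b = initial_gaussian_belief(params)
        t = DecisionTrial(dm=5, ds=5)
        harm = gaussian_update(b, t, True, params)
        no_harm = gaussian_update(b, t, False, params)
        assert harm.mu < b.mu  # harmful choice implies lower harm aversion
        assert no_harm.mu > b.mu

    def test_larger_prior_uncertainty_larger_update(self):
        params = InferenceParams(omega=-50.0, beta_pred=3.0)
        t = DecisionTrial(dm=6, ds=5)
        tight = BeliefState(mu=0.5, sigma=0.005, trial_index=0)
        wide = BeliefState(mu=0.5, sigma=0.05, trial_index=0)
        d_tight = abs(gaussian_update(tight, t, True, params).mu - 0.5)
        d_wide = abs(gaussian_update(wide, t, True, params).mu - 0.5)
        assert d_wide > d_tight

    def test_variance_shrinks_on_informative_trial(self):
        params = InferenceParams(omega=-50.0, beta_pred=3.0)
        b = initial_gaussian_belief(params)
        post = gaussian_update(b, DecisionTrial(dm=6, ds=5), True, params)
        assert post.sigma < b.sigma

    def test_tracks_grid_oracle_on_benchmark_session(self, benchmark_session):
        agent, session = benchmark_session
        params = InferenceParams(omega=-4.0, beta_pred=3.0)
        tg = run_learner(session, params, "grid")
        ta = run_learner(session, params, "gaussian")
        assert np.mean(np.abs(tg.mu - ta.mu)) < 0.05
        assert np.corrcoef(tg.mu, ta.mu)[0, 1] > 0.95


class TestRescorlaWagner:
    @pytest.mark.parametrize(
        "p, y, alpha, expected",
        [(0.5, True, 0.0, 0.5), (0.5, True, 1.0, 1.0), (0.5, True, 0.1, 0.55)],
    )
    def test_update_values(self, p, y, alpha, expected):
        assert rw_update(p, y, alpha) == pytest.approx(expected)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rw_update(0.5, True, 1.5)


class TestRunLearner:
    def test_empty_session_returns_prior_only(self):
        traj = run_learner([], InferenceParams(), "gaussian")
        assert len(traj.mu) == 0
        assert traj.mu0 == 0.5

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            run_learner([], InferenceParams(), "kalman")

    def test_rw_has_no_uncertainty_trajectory(self):
        _, session = make_session("good", 10, seed=2)
        traj = run_learner(session, InferenceParams(alpha=0.3), "rw")
        assert traj.sigma is None
        assert len(traj.mu) == 10

    def test_learner_converges_to_agent_kappa(self):
        hits = 0
        for seed in range(10):
            agent, session = make_session("good", 120, seed=seed)
            params = InferenceParams(
                omega=-8.0, beta_pred=3.0, beta_agent=agent.beta_agent
            )
            traj = run_learner(session, params, "grid")
            hits += abs(traj.mu[-1] - agent.kappa_o) < 0.05
        assert hits >= 9

    def test_deterministic(self):
        _, session = make_session("bad", 20, seed=4)
        p = InferenceParams(omega=-4.0, beta_pred=3.0)
        a = run_learner(session, p, "gaussian")
        b = run_learner(session, p, "gaussian")
        np.testing.assert_array_equal(a.mu, b.mu)


class TestFitInference:
    def _make_subject(self, gen_params, seed, variant="gaussian"):
        rng = np.random.default_rng(seed)
        sessions = {}
        for a in ("good", "bad"):
            sess = synthetic.generate_inference_session(
                synthetic.make_agent(a),
                synthetic.generate_decision_trials(60, seed=rng),
                learner=gen_params,
                seed=rng,
                variant=variant,
            )
            sessions[a] = sess.records
        return sessions

    def test_parameter_recovery(self):
        gen = InferenceParams(omega=-4.0, beta_pred=3.0)
        omegas, betas = [], []
        for s in range(8):
            fit = fit_inference(self._make_subject(gen, 200 + s), variant="gaussian",
                                seed=s)
            omegas.append(fit.params.omega)
            betas.append(fit.params.beta_pred)
        assert abs(np.median(omegas) - (-4.0)) < 1.0
        assert abs(np.median(betas) - 3.0) / 3.0 < 0.3

    def test_constant_predictions_flagged(self):
        _, session = make_session("good", 20, seed=5)
        session = [
            PredictionRecord(
                trial=r.trial, agent_choice=r.agent_choice,
                participant_prediction=True,
                feedback_correct=(r.agent_choice is True),
            )
            for r in session
        ]
        fit = fit_inference(session, variant="rw", seed=0)
        assert "constant_predictions" in fit.flags

    def test_missing_predictions_rejected(self):
        _, session = make_session("good", 5, seed=6)
        with pytest.raises(ValueError, match="without predictions"):
            fit_inference(session, variant="gaussian")

    def test_per_agent_omega_ordering_recovered(self):
        ok = 0
        for s in range(8):
            rng = np.random.default_rng(300 + s)
            sessions = {}
            for a, om in (("good", -5.0), ("bad", -2.5)):
                sess = synthetic.generate_inference_session(
                    synthetic.make_agent(a),
                    synthetic.generate_decision_trials(60, seed=rng),
                    learner=InferenceParams(omega=om, beta_pred=3.0),
                    seed=rng,
                )
                sessions[a] = sess.records
            fit = fit_inference(sessions, variant="gaussian", per_agent_omega=True,
                                seed=s)
            ok += fit.omega_by_agent["bad"] > fit.omega_by_agent["good"]
        assert ok >= 6  # beliefs about the more volatile agent revise faster


class TestCompareModels:
    def test_tie_reported_and_broken_toward_fewer_params(self):
        a = inf.InferenceFit("gaussian", InferenceParams(), None, -10.0, 20, 2,
                             24.0, 25.0, [])
        b = inf.InferenceFit("rw", InferenceParams(), None, -11.0, 20, 1,
                             24.0, 25.0, [])
        tbl = compare_models({"gaussian": a, "rw": b})
        assert tbl["tie"].all()
        assert tbl.loc[tbl["best"], "variant"].iloc[0] == "rw"

    def test_mismatched_trial_counts_rejected(self):
        a = inf.InferenceFit("gaussian", InferenceParams(), None, -10, 20, 2, 1, 1, [])
        b = inf.InferenceFit("rw", InferenceParams(), None, -10, 30, 1, 1, 1, [])
        with pytest.raises(ValueError, match="different trial counts"):
            compare_models({"gaussian": a, "rw": b})

    def test_generating_model_preferred(self):
        # data from the Bayesian learner should favor it over rw, and vice versa
        maker = TestFitInference()
        gauss_wins = rw_wins = 0
        n = 6
        for s in range(n):
            sess = maker._make_subject(InferenceParams(omega=-4.0, beta_pred=3.0),
                                       400 + s)
            fits = {v: fit_inference(sess, variant=v, seed=s) for v in ("gaussian", "rw")}
            tbl = compare_models(fits)
            gauss_wins += tbl.loc[tbl["best"], "variant"].iloc[0] == "gaussian"
            sess = maker._make_subject(InferenceParams(alpha=0.25), 500 + s,
                                       variant="rw")
            fits = {v: fit_inference(sess, variant=v, seed=s) for v in ("gaussian", "rw")}
            tbl = compare_models(fits)
            rw_wins += tbl.loc[tbl["best"], "variant"].iloc[0] == "rw"
        assert gauss_wins >= n - 1
        assert rw_wins > n / 2


class TestProbes:
    def test_midpoint_belief_maps_to_scale_midpoint(self):
        b = BeliefState(mu=0.5, sigma=0.01, trial_index=0)
        probe = probe_prediction(b)
        assert probe.character == pytest.approx(50.0)

    def test_uncertainty_monotone_in_sigma(self):
        lo = probe_prediction(BeliefState(mu=0.5, sigma=0.01, trial_index=0))
        hi = probe_prediction(BeliefState(mu=0.5, sigma=0.05, trial_index=0))
        assert hi.uncertainty > lo.uncertainty

    def test_rating_map_round_trip(self):
        true_map = RatingMap(char_intercept=5.0, char_slope=80.0,
                             unc_intercept=2.0, unc_slope=900.0)
        rng = np.random.default_rng(1)
        mus = rng.uniform(0.2, 0.8, 30)
        sigmas = rng.uniform(0.005, 0.06, 30)
        probes = [
            probe_prediction(
                BeliefState(mu=float(m), sigma=float(s), trial_index=i), true_map
            )
            for i, (m, s) in enumerate(zip(mus, sigmas))
        ]
        fitted = fit_rating_map(probes, mus, sigmas)
        assert abs(fitted.char_slope - 80.0) / 80.0 < 0.05
        assert abs(fitted.unc_slope - 900.0) / 900.0 < 0.05
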