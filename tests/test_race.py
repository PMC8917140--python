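"""Analytic race likelihood against quadrature and simulation oracles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

from stoprace.generative import ExGaussParams, RaceParams, simulate_race_trials
from stoprace.race import (
    RaceData,
    dataset_loglik,
    loglik_go_omission,
    loglik_go_response,
    loglik_signal_respond,
    loglik_successful_stop,
    stop_success_probability,
)
from stoprace.task import SessionConfig, run_session


class TestGoTerms:
    def test_no_failures_reduces_to_exgauss_density(self, control_race_params):
        p = replace(control_race_params, gf=0.0)
        ref = stats.exponnorm.logpdf(446.0, p.go.tau / p.go.sigma,
                                     loc=p.go.mu, scale=p.go.sigma)
        assert loglik_go_response(446.0, p) == pytest.approx(ref, abs=1e-10)

    def test_certain_omission_has_zero_response_likelihood(
            self, control_race_params):
        p = replace(control_race_params, gf=1.0)
        assert loglik_go_response(446.0, p) == -np.inf

    def test_mixture_offset(self, control_race_params):
        p = replace(control_race_params, gf=0.1)
        base = replace(control_race_params, gf=0.0)
        assert loglik_go_response(446.0, p) == pytest.approx(
            loglik_go_response(446.0, base) + np.log(0.9), abs=1e-12)

    def test_omission_terms(self, control_race_params):
        p = replace(control_race_params, gf=0.5, max_rt=1e9)
        assert loglik_go_omission(p) == pytest.approx(np.log(0.5), abs=1e-9)
        p0 = replace(control_race_params, gf=0.0, max_rt=1e9)
        assert loglik_go_omission(p0) < -30.0
        # finite-deadline mass equals the ex-Gaussian survival (cdf oracle)
        p1 = replace(control_race_params, gf=0.0, max_rt=600.0)
        sf = stats.exponnorm.sf(600.0, p1.go.tau / p1.go.sigma,
                                loc=p1.go.mu, scale=p1.go.sigma)
        assert loglik_go_omission(p1) == pytest.approx(np.log(sf), abs=1e-9)


class TestSignalRespond:
    def test_trigger_failure_collapses_to_go_density(self, control_race_params):
        p = replace(control_race_params, tf=1.0)
        assert loglik_signal_respond(446.0, 250.0, p) == pytest.approx(
            loglik_go_response(446.0, p), abs=1e-12)

    def test_response_before_ssd_cannot_have_raced(self, control_race_params):
        """rt <= ssd: the stop runner has not started, survival = 1."""
        p = control_race_params
        assert loglik_signal_respond(200.0, 250.0, p) == pytest.approx(
            loglik_go_response(200.0, p), abs=1e-12)


class TestSuccessfulStop:
    def test_impossible_success_at_huge_ssd(self, control_race_params):
        p = replace(control_race_params, tf=0.0, gf=0.0)
        assert loglik_successful_stop(50_000.0, p) < np.log(1e-4)

    def test_degenerate_fast_stop_always_wins(self):
        p = RaceParams(go=ExGaussParams(400.0, 40.0, 40.0),
                       stop=ExGaussParams(0.001, 1e-4, 1e-4),
                       tf=0.0, gf=0.0)
        assert loglik_successful_stop(0.0, p) > np.log(0.999)

    @pytest.mark.parametrize("ssd", [100.0, 200.0, 300.0])
    def test_matches_simulation_frequency(self, ssd, rng,
                                          control_race_params):
        p = control_race_params
        n = 200_000
        outcome, _ = simulate_race_trials(p, ssd, n, rng)
        freq = 1.0 - outcome.mean()
        analytic = stop_success_probability(ssd, p)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(freq - analytic) < 3 * se


class TestTotalProbability:
    @pytest.mark.parametrize("ssd", [50.0, 250.0, 450.0])
    def test_stop_trial_mass_sums_to_one(self, ssd, control_race_params):
        p = control_race_params
        dens, _ = integrate.quad(
            lambda t: np.exp(loglik_signal_respond(t, ssd, p)),
            1e-9, p.max_rt, limit=300)
        total = dens + stop_success_probability(ssd, p)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_continuous_in_parameters(self, control_race_params):
        """Finite-difference smoke test on the interior of the domain."""
        p = control_race_params
        base = loglik_signal_respond(446.0, 250.0, p)
        for eps in (1e-4, 1e-5):
            bumped = replace(
                p, stop=ExGaussParams(p.stop.mu + eps, p.stop.sigma,
                                      p.stop.tau))
            assert abs(loglik_signal_respond(446.0, 250.0, bumped)
                       - base) < 1e-2


class TestDatasetLoglik:
    def test_empty_and_single(self, control_race_params):
        p = control_race_params
        empty = RaceData(np.array([]), 0, np.array([]), np.array([]),
                         np.array([]), np.array([]))
        assert dataset_loglik(empty, p) == 0.0
        single = RaceData(np.array([446.0]), 0, np.array([]), np.array([]),
                          np.array([]), np.array([]))
        assert dataset_loglik(single, p) == pytest.approx(
            loglik_go_response(446.0, p))

    def test_mixed_subjects_rejected(self, control_race_params):
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=50)
        recs = (run_session(cfg, control_race_params, 1, participant_id="a")
                + run_session(cfg, control_race_params, 2,
                              participant_id="b"))
        with pytest.raises(ValueError, match="multiple subjects"):
            dataset_loglik(recs, control_race_params)

    def test_generating_parameters_dominate_perturbed(
            self, control_race_params):
        """The likelihood at the generating parameters beats +-30%
        perturbations in nearly every simulated replicate."""
        p = control_race_params
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=200)
        rng = np.random.default_rng(77)
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            recs = run_session(cfg, p, seed=rng.integers(2**31))
            data = RaceData.from_records(recs)
            f = 1.3 if r % 2 == 0 else 0.7
            pert = RaceParams(
                go=ExGaussParams(p.go.mu * f, p.go.sigma * f, p.go.tau * f),
                stop=ExGaussParams(p.stop.mu * f, p.stop.sigma * f,
                                   p.stop.tau * f),
                tf=min(p.tf * f, 1.0), gf=min(p.gf * f, 1.0))
            if dataset_loglik(data, p) >= dataset_loglik(data, pert):
                wins += 1
        assert wins >= 0.95 * n_rep
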