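"""DE-MCMC sampler, convergence diagnostics, and hierarchical fits."""

import numpy as np
import pytest

from stoprace.generative import ExGaussParams, RaceParams
from stoprace.hier import (
    RaceModelSpec,
    SamplerConfig,
    de_mcmc_sample,
    de_mcmc_step,
    effective_sample_size,
    fit_hierarchical,
    gelman_rubin,
    group_posterior_means,
    posterior_summary,
)
from stoprace.race import RaceData
from stoprace.task import SessionConfig, run_session


def _standard_normal_logp(x):
    return -0.5 * (x**2).sum(axis=1)


class TestDEStep:
    def test_identity_proposal_always_accepted(self, rng):
        states = rng.normal(size=(8, 3))
        logp = _standard_normal_logp(states)
        out, lp, acc = de_mcmc_step(states, logp, _standard_normal_logp, rng,
                                    gamma=0.0, jitter=0.0)
        assert acc.all()
        np.testing.assert_array_equal(out, states)

    def test_uphill_proposals_certain(self, rng):
        """A proposal with higher density is accepted with probability 1:
        force it by supplying a target that rewards any move."""
        states = np.zeros((6, 2))
        calls = {"n": 0}

        def logp_fn(x):
            calls["n"] += 1
            # first call scores the proposals higher than the current -1
            return np.full(x.shape[0], 0.0)

        out, lp, acc = de_mcmc_step(states, np.full(6, -1.0), logp_fn, rng,
                                    jitter=1e-3)
        assert acc.all()
        assert (lp == 0.0).all()

    def test_samples_standard_normal(self, rng):
        init = rng.normal(0.0, 3.0, size=(33, 1))
        s = de_mcmc_sample(_standard_normal_logp, init, 2500, rng)
        post = s[:, 500:, 0]
        assert abs(post.mean()) < 0.05
        assert abs(post.var() - 1.0) < 0.1

    def test_samples_correlated_target(self, rng):
        """Banana-style curved target: the DE proposals adapt to it."""
        def logp(x):
            y = x.copy()
            y[:, 1] = x[:, 1] - x[:, 0] ** 2
            return -0.5 * (y[:, 0] ** 2 / 4.0 + y[:, 1] ** 2)

        init = rng.normal(0.0, 1.0, size=(40, 2))
        s = de_mcmc_sample(logp, init, 4000, rng)
        x0 = s[:, 1000:, 0].ravel()
        x1 = s[:, 1000:, 1].ravel()
        assert abs(x0.mean()) < 0.15
        assert abs(x0.var() - 4.0) < 0.6
        # E[x1] = E[x0^2] = 4
        assert abs(x1.mean() - 4.0) < 0.6


class TestGelmanRubin:
    def test_hand_computed_two_chain_toy(self):
        """Explicit arithmetic: chains {0,2} and {1,3}."""
        chains = np.array([[0.0, 2.0], [1.0, 3.0]])
        n = 2
        w = (np.var([0.0, 2.0], ddof=1) + np.var([1.0, 3.0], ddof=1)) / 2.0
        b_over_n = np.var([1.0, 2.0], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected)

    def test_iid_chains_converge_to_one(self, rng):
        chains = rng.normal(size=(8, 4000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0.0, 1.0, 200),
                           rng.normal(10.0, 1.0, 200)])
        assert gelman_rubin(chains) > 1.1

    def test_zero_within_variance_undefined(self):
        assert np.isnan(gelman_rubin(np.ones((3, 10))))


class TestESS:
    def test_iid_chains_near_total(self, rng):
        x = rng.normal(size=(8, 4000))
        ess = effective_sample_size(x)
        assert 0.8 * x.size <= ess <= x.size

    def test_ar1_matches_closed_form(self, rng):
        rho, n, m = 0.9, 4000, 8
        x = np.empty((m, n))
        for c in range(m):
            e = rng.normal(size=n)
            x[c, 0] = e[0]
            for t in range(1, n):
                x[c, t] = rho * x[c, t - 1] + np.sqrt(1 - rho**2) * e[t]
        expected = x.size * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_constant_chain_undefined(self):
        assert np.isnan(effective_sample_size(np.full((3, 50), 2.5)))


def _tiny_race_datasets(n_subjects=3, n_trials=150, seed=0):
    p = RaceParams(go=ExGaussParams(360.0, 60.0, 86.0),
                   stop=ExGaussParams(109.0, 36.0, 34.0), tf=0.05, gf=0.01)
    cfg = SessionConfig(task="classical", condition="control",
                        n_trials=n_trials)
    return [RaceData.from_records(
        run_session(cfg, p, seed=seed + i, participant_id=f"s{i}"))
        for i in range(n_subjects)]


_TINY = SamplerConfig(n_chains=8, n_burn=30, n_keep=10, thin=1)


class TestHierarchicalFit:
    def test_same_seed_identical_chains(self):
        datas = _tiny_race_datasets()
        a = fit_hierarchical(datas, RaceModelSpec(), _TINY, seed=5)
        b = fit_hierarchical(datas, RaceModelSpec(), _TINY, seed=5)
        np.testing.assert_array_equal(a.subj, b.subj)
        np.testing.assert_array_equal(a.hyper_loc, b.hyper_loc)

    def test_single_subject_fit_runs(self):
        datas = _tiny_race_datasets(n_subjects=1)
        ch = fit_hierarchical(datas, RaceModelSpec(), _TINY, seed=2)
        assert ch.subj.shape == (8, 10, 1, 8)

    def test_group_means_on_reporting_scale(self):
        datas = _tiny_race_datasets()
        ch = fit_hierarchical(datas, RaceModelSpec(), _TINY, seed=3)
        means = group_posterior_means(ch)
        # probabilities come back as percent, locations in ms
        assert 0.0 <= means["tf"] <= 100.0
        assert 100.0 <= means["mu_go"] <= 900.0

    def test_too_short_fit_is_flagged_unconverged(self):
        """Diagnostics honesty: a handful of iterations cannot pass R-hat."""
        datas = _tiny_race_datasets()
        short = SamplerConfig(n_chains=8, n_burn=2, n_keep=10, thin=1)
        ch = fit_hierarchical(datas, RaceModelSpec(), short, seed=7)
        assert max(v for v in ch.rhat().values() if np.isfinite(v)) > 1.1
        with pytest.raises(RuntimeError, match="unconverged"):
            posterior_summary(ch)
        df = posterior_summary(ch, allow_unconverged=True)
        assert set(df["parameter"]) == set(ch.param_names)
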