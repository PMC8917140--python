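"""Trial sequences, the SSD staircase, and simulated sessions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoprace.generative import ExGaussParams, RaceParams
from stoprace.task import (
    SessionConfig,
    StaircaseState,
    generate_trial_sequence,
    run_session,
    sensorial_stimulus_schedule,
    staircase_update,
)


class TestTrialSequence:
    @pytest.mark.parametrize("n,p,n_stop", [(100, 0.3, 30), (50, 0.3, 15),
                                            (10, 0.0, 0)])
    def test_exact_composition(self, n, p, n_stop):
        seq = generate_trial_sequence(n, p, seed=7)
        assert seq.count("stop") == n_stop
        assert len(seq) == n

    @given(n_go=st.integers(10, 120), n_stop=st.integers(0, 25),
           seed=st.integers(0, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_constraints_hold_for_any_admissible_composition(
            self, n_go, n_stop, seed):
        """First two trials are go; never more than 3 consecutive stops."""
        n = n_go + n_stop
        seq = generate_trial_sequence(n, n_stop / n, seed=seed)
        assert seq.count("stop") == n_stop
        if n_stop:
            assert seq[0] == seq[1] == "go"
        run = 0
        for t in seq:
            run = run + 1 if t == "stop" else 0
            assert run <= 3

    def test_non_integral_composition_rejected(self):
        with pytest.raises(ValueError, match="not an integer"):
            generate_trial_sequence(10, 0.25, seed=0)

    def test_deterministic_per_seed(self):
        a = generate_trial_sequence(100, 0.3, seed=42)
        b = generate_trial_sequence(100, 0.3, seed=42)
        c = generate_trial_sequence(100, 0.3, seed=43)
        assert a == b
        assert a != c


class TestStaircase:
    def test_moves_and_clamps(self):
        s = StaircaseState(ssd=200.0)
        assert staircase_update(s, "inhibited").ssd == 275.0
        assert staircase_update(s, "responded").ssd == 125.0
        at_floor = StaircaseState(ssd=0.0)
        assert staircase_update(at_floor, "responded").ssd == 0.0
        at_ceil = StaircaseState(ssd=1125.0)
        assert staircase_update(at_ceil, "inhibited").ssd == 1125.0

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            staircase_update(StaircaseState(), "maybe")


class TestStimulusSchedule:
    def test_balanced_counts(self):
        sched = sensorial_stimulus_schedule(60, (-3, -2, -1, 1, 2, 3), seed=1)
        values, counts = np.unique(sched, return_counts=True)
        assert set(values) == {-3, -2, -1, 1, 2, 3}
        assert (counts == 10).all()

    def test_one_of_each_when_exact(self):
        sched = sensorial_stimulus_schedule(6, (-3, -2, -1, 1, 2, 3), seed=5)
        assert sorted(sched) == [-3, -2, -1, 1, 2, 3]

    def test_empty_cases(self):
        assert sensorial_stimulus_schedule(0, (1, 2), seed=0) == []
        with pytest.raises(ValueError):
            sensorial_stimulus_schedule(10, (), seed=0)


class TestSessionConfig:
    def test_defaults_and_invariants(self):
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=100)
        assert cfg.max_rt == 1200.0 and cfg.p_stop == 0.3
        assert cfg.n_stop == 30 and cfg.n_go == 70
        with pytest.raises(ValueError, match="angle_set"):
            SessionConfig(task="sensorial", condition="control", n_trials=100)
        with pytest.raises(ValueError, match="integer"):
            SessionConfig(task="classical", condition="control", n_trials=10,
                          p_stop=0.25)


class TestRunSession:
    def test_forced_inhibitions_raise_ssd_in_steps(self):
        """A slow go against an instant stop inhibits every early stop trial,
        so the SSD climbs by exactly one step per stop trial."""
        agent = RaceParams(go=ExGaussParams(1000.0, 10.0, 10.0),
                           stop=ExGaussParams(1.0, 0.1, 0.1), tf=0.0)
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=100)
        recs = run_session(cfg, agent, seed=3)
        ssds = [r.ssd for r in recs if r.trial_type == "stop"][:8]
        assert ssds == [200.0 + 75.0 * i for i in range(8)]
        # stop trials remain inhibited until the SSD approaches the slow
        # go RT; those with a comfortable margin are all successful stops
        assert all(r.response == "none" for r in recs
                   if r.trial_type == "stop" and r.ssd <= 700.0)

    def test_bitwise_determinism(self, control_race_params):
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=100)
        a = run_session(cfg, control_race_params, seed=11)
        b = run_session(cfg, control_race_params, seed=11)
        assert a == b

    def test_record_invariants(self, control_race_params):
        cfg = SessionConfig(task="sensorial", condition="canal", n_trials=50,
                            angle_set=(-3, -2, -1, 1, 2, 3))
        recs = run_session(cfg, control_race_params, seed=9)
        assert len(recs) == 50
        for r in recs:
            if r.trial_type == "go":
                assert r.ssd is None
            else:
                assert r.ssd is not None and r.ssd >= 0
            if r.response == "none":
                assert r.rt is None and r.correct is None
            else:
                assert 0 < r.rt <= cfg.max_rt

    def test_staircase_tracks_half_inhibition(self, control_race_params):
        """One-up one-down tracking pulls long-run P(respond | stop) to 1/2
        for a trigger-failure-free stationary agent."""
        from dataclasses import replace
        agent = replace(control_race_params, tf=0.0, gf=0.0)
        cfg = SessionConfig(task="classical", condition="control",
                            n_trials=2000, p_stop=0.5)
        recs = run_session(cfg, agent, seed=21)
        stop = [r for r in recs if r.trial_type == "stop"]
        p_resp = np.mean([r.response != "none" for r in stop])
        assert abs(p_resp - 0.5) < 0.05
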