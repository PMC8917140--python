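"""Stop-signal session engine: trial sequences, SSD staircase, simulated runs.

A session is a fixed-composition sequence of go and stop trials (exactly
``n_trials * p_stop`` stop trials).  On stop trials the stop signal follows
the go stimulus after the stop-signal delay (SSD), tracked by a one-up
one-down staircase: +step after a successful inhibition, -step after a failed
one, so that long-run inhibition accuracy converges to 50%.  Defaults follow
the centrifuge study design this package models: staircase start 200 ms, step
75 ms, response deadline 1200 ms, 30% stop trials, 100 trials in the Control
condition and 50 in the Canal/Otolith conditions (rotation-time limited).

Two agent kinds can drive a simulated session:

* a :class:`~stoprace.generative.RaceParams` agent — ex-Gaussian go RTs racing
  an ex-Gaussian stop process (no accuracy model: responded go trials are
  scored correct);
* a :class:`DDMAgent` — diffusion Go decisions (accuracy + RT) whose go RT
  races an ex-Gaussian stop process with trigger/go-failure mixtures.

Fixation (250 ms) and inter-trial interval (250 ms) are carried as session
metadata only; they enter no likelihood.  Go-stimulus/response-side
counterbalancing is likewise recorded, not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .generative import (
    DDMParams,
    ExGaussParams,
    RaceParams,
    sample_exgauss,
    simulate_ddm_trials,
)

__all__ = [
    "SessionConfig",
    "StaircaseState",
    "TrialRecord",
    "DDMAgent",
    "default_session_config",
    "generate_trial_sequence",
    "staircase_update",
    "sensorial_stimulus_schedule",
    "run_session",
]

TASKS = ("classical", "sensorial")
CONDITIONS = ("control", "canal", "otolith")
DEFAULT_ANGLES = (-3, -2, -1, 1, 2, 3)
MAX_CONSECUTIVE_STOPS = 3
LEAD_IN_GO_TRIALS = 2


@dataclass(frozen=True)
class SessionConfig:
    """One session's design constants; times in ms."""

    task: str
    condition: str
    n_trials: int
    p_stop: float = 0.3
    max_rt: float = 1200.0
    fixation_ms: float = 250.0
    iti_ms: float = 250.0
    angle_set: tuple = ()

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not (0.0 <= self.p_stop < 1.0):
            raise ValueError("p_stop must be in [0, 1)")
        n_stop = self.n_trials * self.p_stop
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ValueError(
                f"n_trials * p_stop = {n_stop} is not an integer count of "
                "stop trials; the composition is exact, not Bernoulli")
        if (self.task == "sensorial") != bool(self.angle_set):
            raise ValueError("angle_set must be nonempty iff task='sensorial'")

    @property
    def n_stop(self) -> int:
        return int(round(self.n_trials * self.p_stop))

    @property
    def n_go(self) -> int:
        return self.n_trials - self.n_stop


def default_session_config(task: str, condition: str) -> SessionConfig:
    """Study defaults: 100 trials (control) / 50 (canal, otolith), 30% stop,
    angles +-1/2/3 degrees for the sensorial task."""
    n = 100 if condition == "control" else 50
    angles = DEFAULT_ANGLES if task == "sensorial" else ()
    return SessionConfig(task=task, condition=condition, n_trials=n,
                         angle_set=angles)


@dataclass(frozen=True)
class StaircaseState:
    """SSD staircase: current delay, step, and clamp bounds (ms)."""

    ssd: float = 200.0
    step: float = 75.0
    initial: float = 200.0
    lower_bound: float = 0.0
    upper_bound: float = 1125.0

    def __post_init__(self) -> None:
        if not (self.lower_bound <= self.ssd <= self.upper_bound):
            raise ValueError(
                f"ssd {self.ssd} outside [{self.lower_bound}, {self.upper_bound}]")


def staircase_update(state: StaircaseState, stop_trial_outcome: str
                     ) -> StaircaseState:
    """One-up one-down move: 'inhibited' -> ssd + step, 'responded' ->
    ssd - step, clamped to the state's bounds."""
    if stop_trial_outcome == "inhibited":
        new = state.ssd + state.step
    elif stop_trial_outcome == "responded":
        new = state.ssd - state.step
    else:
        raise ValueError(
            f"outcome must be 'inhibited' or 'responded', got "
            f"{stop_trial_outcome!r}")
    new = min(max(new, state.lower_bound), state.upper_bound)
    return replace(state, ssd=new)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial — the pipeline's atom.  ``ssd``/``rt`` are None
    where absent (go trials have no SSD; unresponded trials no RT);
    ``correct`` is None on unresponded trials."""

    participant_id: str
    task: str
    condition: str
    trial_index: int
    trial_type: str
    stimulus: object
    ssd: Optional[float]
    response: str
    rt: Optional[float]
    correct: Optional[bool]

    def __post_init__(self) -> None:
        if self.trial_type == "go" and self.ssd is not None:
            raise ValueError("go trials carry no SSD")
        if self.response == "none" and self.rt is not None:
            raise ValueError("response='none' implies rt absent")
        if self.response != "none" and self.rt is None:
            raise ValueError("a responded trial needs an RT")


@dataclass(frozen=True)
class DDMAgent:
    """Generative agent whose Go decision is a diffusion and whose stop
    process is an ex-Gaussian racing the go RT, with trigger failures ``tf``
    and go failures ``gf``."""

    ddm: DDMParams
    stop: ExGaussParams
    tf: float = 0.0
    gf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tf", "gf"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")


Agent = Union[RaceParams, DDMAgent]


def _rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))


def generate_trial_sequence(n_trials: int, p_stop: float, seed) -> list:
    """Pseudo-randomized go/stop sequence with exact composition.

    Constraints: the first two trials are go, and no more than three stop
    trials run consecutively.  Stops are assigned to the capacity-3 gaps that
    follow the 2nd..last go trial, so every admissible composition
    (n_stop <= 3 * (n_go - 1)) can be generated; deterministic per seed.
    """
    n_stop = n_trials * p_stop
    if abs(n_stop - round(n_stop)) > 1e-9:
        raise ValueError(
            f"n_trials * p_stop = {n_stop} is not an integer; exact "
            "composition requires an integral stop-trial count")
    n_stop = int(round(n_stop))
    n_go = n_trials - n_stop
    if n_stop == 0:
        return ["go"] * n_trials
    if n_go < LEAD_IN_GO_TRIALS:
        raise ValueError("need at least two go trials before the first stop")
    n_gaps = n_go - 1
    if n_stop > MAX_CONSECUTIVE_STOPS * n_gaps:
        raise ValueError(
            f"{n_stop} stop trials cannot be placed with at most "
            f"{MAX_CONSECUTIVE_STOPS} consecutive among {n_go} go trials")
    rng = _rng_from(seed)
    slots = np.repeat(np.arange(n_gaps), MAX_CONSECUTIVE_STOPS)
    rng.shuffle(slots)
    counts = np.bincount(slots[:n_stop], minlength=n_gaps)
    seq = ["go", "go"]
    seq += ["stop"] * int(counts[0])
    for g in range(1, n_gaps):
        seq.append("go")
        seq += ["stop"] * int(counts[g])
    assert len(seq) == n_trials
    return seq


def sensorial_stimulus_schedule(n_go_trials: int, angle_set: Sequence[float],
                                seed) -> list:
    """Balanced, seed-shuffled assignment of signed angles (degrees from the
    reference apparent zenith) to go trials; counts differ by at most one."""
    angles = list(angle_set)
    if not angles:
        raise ValueError("angle_set must be nonempty")
    if n_go_trials == 0:
        return []
    rng = _rng_from(seed)
    base, rem = divmod(n_go_trials, len(angles))
    sched = angles * base + list(
        rng.choice(angles, size=rem, replace=False)) if rem else angles * base
    sched = list(sched)
    rng.shuffle(sched)
    return sched


def _classical_stimuli(n: int, rng) -> list:
    return [("ring", "circle")[i] for i in rng.integers(0, 2, size=n)]


_CORRECT_SIDE = {"ring": "left", "circle": "right"}


def _correct_side(task: str, stimulus) -> str:
    if task == "classical":
        return _CORRECT_SIDE[stimulus]
    return "left" if stimulus > 0 else "right"   # above RAZ -> left key


def run_session(config: SessionConfig, agent: Agent, seed,
                participant_id: str = "s01",
                staircase: Optional[StaircaseState] = None) -> list:
    """Simulate one full session: sequence, staircase-driven SSDs, and one
    :class:`TrialRecord` per trial.  Deterministic per (config, agent, seed).

    Go responses slower than the deadline are recorded as omissions
    (response='none').  The staircase resets to its initial SSD each session
    unless an explicit ``staircase`` state is passed in.
    """
    rng = _rng_from(seed)
    seq = generate_trial_sequence(config.n_trials, config.p_stop, rng)
    n = config.n_trials

    # stimuli for every trial (stop trials show the go stimulus too)
    if config.task == "sensorial":
        stimuli = sensorial_stimulus_schedule(n, config.angle_set, rng)
    else:
        stimuli = _classical_stimuli(n, rng)

    # pre-draw latent per-trial quantities; only SSD is sequential
    if isinstance(agent, RaceParams):
        go_rt = sample_exgauss(agent.go, n, rng)
        stop_lat = np.maximum(sample_exgauss(agent.stop, n, rng), 0.0)
        gf_flag = rng.random(n) < agent.gf
        tf_flag = rng.random(n) < agent.tf
        correct_flag = np.ones(n, dtype=bool)
    elif isinstance(agent, DDMAgent):
        boundary, go_rt, censored = simulate_ddm_trials(agent.ddm, n, rng)
        correct_flag = boundary == 1
        go_rt = np.where(censored, np.inf, go_rt)
        stop_lat = np.maximum(sample_exgauss(agent.stop, n, rng), 0.0)
        gf_flag = rng.random(n) < agent.gf
        tf_flag = rng.random(n) < agent.tf
    else:
        raise TypeError(f"unsupported agent type {type(agent).__name__}")

    state = staircase if staircase is not None else StaircaseState(
        upper_bound=config.max_rt - StaircaseState.step)
    records = []
    for i, kind in enumerate(seq):
        stim = stimuli[i]
        side = _correct_side(config.task, stim)
        responds_go = (not gf_flag[i]) and (0.0 < go_rt[i] <= config.max_rt)
        if kind == "go":
            if responds_go:
                resp = side if correct_flag[i] else (
                    "right" if side == "left" else "left")
                rec = TrialRecord(participant_id, config.task,
                                  config.condition, i, "go", stim, None,
                                  resp, float(go_rt[i]), bool(correct_flag[i]))
            else:
                rec = TrialRecord(participant_id, config.task,
                                  config.condition, i, "go", stim, None,
                                  "none", None, None)
        else:
            ssd = state.ssd
            responds = responds_go and (
                tf_flag[i] or go_rt[i] < ssd + stop_lat[i])
            if responds:
                resp = side if correct_flag[i] else (
                    "right" if side == "left" else "left")
                rec = TrialRecord(participant_id, config.task,
                                  config.condition, i, "stop", stim,
                                  float(ssd), resp, float(go_rt[i]),
                                  bool(correct_flag[i]))
                state = staircase_update(state, "responded")
            else:
                rec = TrialRecord(participant_id, config.task,
                                  config.condition, i, "stop", stim,
                                  float(ssd), "none", None, None)
                state = staircase_update(state, "inhibited")
        records.append(rec)
    return records
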