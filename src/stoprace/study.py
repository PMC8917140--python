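"""Synthetic study generator: complete datasets with known ground truth.

The raw behavioural data of the vestibular stop-signal study this package
models are not publicly deposited, so every downstream stage is exercised on
synthetic data with the study's structure: 38 participants x 2 tasks
(classical, sensorial) x 3 conditions (Control 100 trials, Canal/Otolith 50),
70% go / 30% stop trials, staircase SSD.  Group-level generating means and
between-subject SDs default to the published per-cell descriptive values for
the stop-side race parameters (mu/sigma/tau of the stop latency, trigger- and
go-failure percentages) and the diffusion Go parameters (a, v, t0, z) — so the
default dataset embodies the reported condition effects (e.g. Canal raises
sigma_Stop and tau_Stop).

The go-side ex-Gaussian generating values are NOT published; when a pure race
agent is requested they are derived from the printed go-RT summaries by a
fixed calibration rule (tau_go = 0.82 * IIV, sigma_go = sqrt(IIV^2 -
tau_go^2), mu_go = RT_Tot - tau_go), which reproduces the printed mean and SD
of go RTs by the ex-Gaussian moment identities.  The default agent instead
couples the diffusion Go process to the ex-Gaussian stop runner
(:class:`~stoprace.task.DDMAgent`), so one simulated session supports both
model fits, and go-RT summaries follow from the published diffusion values.

Between-subject draws are independent truncated normals per cell (the printed
+- values conflate estimation error and true spread; they are used as
between-subject SDs, an acknowledged approximation).  No between-cell
correlation is induced by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .generative import DDMParams, ExGaussParams, RaceParams
from .task import DDMAgent, default_session_config, run_session

__all__ = [
    "StudyBlueprint",
    "CELL_MEANS",
    "CELL_SDS",
    "default_blueprint",
    "null_blueprint",
    "inject_effects",
    "draw_subject_params",
    "generate_study",
]

_CELLS = [(t, c) for t in ("classical", "sensorial")
          for c in ("control", "otolith", "canal")]

# Published per-cell group means.  tf/gf in percent, times in ms; rt_tot/iiv
# are the go-RT summaries the go-side calibration rule consumes.
CELL_MEANS = {
    ("classical", "control"): dict(
        mu_stop=109.0, sigma_stop=36.0, tau_stop=34.0, tf=5.13, gf=0.28,
        a=1.78, v=4.00, t0=224.0, z=0.51, rt_tot=446.0, iiv=105.0),
    ("classical", "otolith"): dict(
        mu_stop=112.0, sigma_stop=26.0, tau_stop=36.0, tf=2.70, gf=0.26,
        a=1.73, v=4.20, t0=238.0, z=0.51, rt_tot=442.0, iiv=96.0),
    ("classical", "canal"): dict(
        mu_stop=106.0, sigma_stop=71.0, tau_stop=59.0, tf=1.91, gf=0.52,
        a=1.74, v=3.91, t0=239.0, z=0.51, rt_tot=461.0, iiv=115.0),
    ("sensorial", "control"): dict(
        mu_stop=126.0, sigma_stop=35.0, tau_stop=42.0, tf=3.38, gf=1.17,
        a=1.35, v=1.49, t0=151.0, z=0.52, rt_tot=417.0, iiv=138.0),
    ("sensorial", "otolith"): dict(
        mu_stop=105.0, sigma_stop=52.0, tau_stop=64.0, tf=1.05, gf=0.63,
        a=1.33, v=1.26, t0=151.0, z=0.50, rt_tot=407.0, iiv=138.0),
    ("sensorial", "canal"): dict(
        mu_stop=89.0, sigma_stop=84.0, tau_stop=90.0, tf=4.37, gf=1.16,
        a=1.26, v=1.43, t0=143.0, z=0.51, rt_tot=416.0, iiv=153.0),
}

# Published between-subject SDs (the printed +- values).
CELL_SDS = {
    ("classical", "control"): dict(
        mu_stop=11.0, sigma_stop=8.0, tau_stop=11.0, tf=6.08, gf=0.64,
        a=0.18, v=0.44, t0=68.0, z=0.05, rt_tot=77.0, iiv=22.0),
    ("classical", "otolith"): dict(
        mu_stop=8.0, sigma_stop=5.0, tau_stop=13.0, tf=2.72, gf=0.86,
        a=0.16, v=0.46, t0=77.0, z=0.06, rt_tot=85.0, iiv=24.0),
    ("classical", "canal"): dict(
        mu_stop=9.0, sigma_stop=19.0, tau_stop=20.0, tf=2.45, gf=1.11,
        a=0.13, v=0.36, t0=62.0, z=0.06, rt_tot=88.0, iiv=50.0),
    ("sensorial", "control"): dict(
        mu_stop=15.0, sigma_stop=7.0, tau_stop=14.0, tf=3.70, gf=1.21,
        a=0.21, v=1.44, t0=78.0, z=0.07, rt_tot=93.0, iiv=31.0),
    ("sensorial", "otolith"): dict(
        mu_stop=9.0, sigma_stop=9.0, tau_stop=22.0, tf=0.53, gf=1.47,
        a=0.24, v=1.40, t0=95.0, z=0.06, rt_tot=107.0, iiv=34.0),
    ("sensorial", "canal"): dict(
        mu_stop=19.0, sigma_stop=17.0, tau_stop=21.0, tf=2.29, gf=1.39,
        a=0.15, v=1.23, t0=85.0, z=0.07, rt_tot=112.0, iiv=60.0),
}

#: go-side calibration: exponential share of the go-RT SD
_GO_TAU_SHARE = 0.82


def go_exgauss_from_summaries(rt_tot: float, iiv: float) -> ExGaussParams:
    """Derive go ex-Gaussian generating values from a printed go-RT mean and
    SD (moment identities: mean = mu + tau, var = sigma^2 + tau^2)."""
    tau = _GO_TAU_SHARE * iiv
    sigma = float(np.sqrt(iiv**2 - tau**2))
    return ExGaussParams(mu=rt_tot - tau, sigma=sigma, tau=tau)


# parameter domains for the truncated-normal subject draws
_DOMAINS = {
    "mu_stop": (0.0, np.inf), "sigma_stop": (1.0, np.inf),
    "tau_stop": (1.0, np.inf), "tf": (0.0, 100.0), "gf": (0.0, 100.0),
    "a": (0.05, np.inf), "v": (-np.inf, np.inf), "t0": (1.0, np.inf),
    "z": (0.01, 0.99),
    "mu_go": (0.0, np.inf), "sigma_go": (1.0, np.inf),
    "tau_go": (1.0, np.inf),
}


@dataclass(frozen=True)
class StudyBlueprint:
    """Design + generating values of one synthetic study."""

    n_participants: int = 38
    trial_counts: dict = field(default_factory=lambda: {
        "control": 100, "canal": 50, "otolith": 50})
    means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in CELL_MEANS.items()})
    sds: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in CELL_SDS.items()})
    agent: str = "ddm"          # 'ddm' (diffusion go + stop race) or 'race'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.agent not in ("ddm", "race"):
            raise ValueError("agent must be 'ddm' or 'race'")
        for cell in _CELLS:
            if cell not in self.means or cell not in self.sds:
                raise ValueError(f"cell {cell} lacks generating values")
        for cond, n in self.trial_counts.items():
            if n <= 0:
                raise ValueError(f"trial count for {cond} must be positive")


def default_blueprint(**kw) -> StudyBlueprint:
    return StudyBlueprint(**kw)


def inject_effects(blueprint: StudyBlueprint, effect_spec: dict
                   ) -> StudyBlueprint:
    """New blueprint with modified cell means.  ``effect_spec`` maps
    (task, condition) to {parameter: new mean}; unknown names are rejected."""
    means = {k: dict(v) for k, v in blueprint.means.items()}
    for cell, updates in effect_spec.items():
        if cell not in means:
            raise KeyError(f"unknown cell {cell}")
        for name, value in updates.items():
            if name not in means[cell]:
                raise KeyError(f"unknown parameter {name!r} in cell {cell}")
            means[cell][name] = float(value)
    return replace(blueprint, means=means)


def null_blueprint(blueprint: StudyBlueprint) -> StudyBlueprint:
    """All conditions share their task's Control means (for specificity /
    type-I-style checks)."""
    spec = {}
    for task in ("classical", "sensorial"):
        ctrl = blueprint.means[(task, "control")]
        for cond in ("canal", "otolith"):
            spec[(task, cond)] = dict(ctrl)
    return inject_effects(blueprint, spec)


def _draw_trunc(mean: float, sd: float, lo: float, hi: float,
                rng: np.random.Generator) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    alpha, beta = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(beta) - stats.norm.cdf(alpha)
    if mass < 0.01:
        raise ValueError(
            f"truncation removes {100 * (1 - mass):.1f}% of the mass for "
            f"mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(stats.truncnorm.rvs(alpha, beta, loc=mean, scale=sd,
                                     random_state=rng))


def draw_subject_params(blueprint: StudyBlueprint, cell,
                        rng: np.random.Generator):
    """One subject's generating parameters for ``cell = (task, condition)``:
    returns (RaceParams, DDMParams), drawn from truncated normals around the
    cell's group means."""
    m, s = blueprint.means[cell], blueprint.sds[cell]

    def draw(name):
        lo, hi = _DOMAINS[name]
        return _draw_trunc(m[name], s[name], lo, hi, rng)

    rt_tot = _draw_trunc(m["rt_tot"], s["rt_tot"], 50.0, np.inf, rng)
    iiv = _draw_trunc(m["iiv"], s["iiv"], 10.0, np.inf, rng)
    go = go_exgauss_from_summaries(rt_tot, iiv)
    stop = ExGaussParams(mu=draw("mu_stop"), sigma=draw("sigma_stop"),
                         tau=draw("tau_stop"))
    race = RaceParams(go=go, stop=stop, tf=draw("tf") / 100.0,
                      gf=draw("gf") / 100.0)
    ddm = DDMParams(a=draw("a"), v=draw("v"), t0=draw("t0"), z=draw("z"))
    return race, ddm


def generate_study(blueprint: StudyBlueprint):
    """Simulate the whole study.

    Returns ``(trials, truth)``: the trial-level table (one row per trial,
    io schema) and the ground-truth table of generating parameters (one row
    per participant x cell).  Fully reproducible from ``blueprint.seed``.
    """
    from .io import records_to_frame

    ss = np.random.SeedSequence(blueprint.seed)
    children = ss.spawn(blueprint.n_participants * len(_CELLS))
    all_records = []
    truth_rows = []
    k = 0
    for p in range(blueprint.n_participants):
        pid = f"p{p + 1:02d}"
        for cell in _CELLS:
            task, cond = cell
            rng = np.random.default_rng(children[k])
            k += 1
            race, ddm = draw_subject_params(blueprint, cell, rng)
            cfg = default_session_config(task, cond)
            n = blueprint.trial_counts[cond]
            if n != cfg.n_trials:
                cfg = replace(cfg, n_trials=n)
            if blueprint.agent == "ddm":
                agent = DDMAgent(ddm=ddm, stop=race.stop, tf=race.tf,
                                 gf=race.gf)
            else:
                agent = race
            recs = run_session(cfg, agent, rng, participant_id=pid)
            all_records.extend(recs)
            truth_rows.append({
                "participant_id": pid, "task": task, "condition": cond,
                "agent": blueprint.agent,
                "mu_go": race.go.mu, "sigma_go": race.go.sigma,
                "tau_go": race.go.tau,
                "mu_stop": race.stop.mu, "sigma_stop": race.stop.sigma,
                "tau_stop": race.stop.tau,
                "tf_pct": race.tf * 100.0, "gf_pct": race.gf * 100.0,
                "a": ddm.a, "v": ddm.v, "t0": ddm.t0, "z": ddm.z,
            })
    return records_to_frame(all_records), pd.DataFrame(truth_rows)
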