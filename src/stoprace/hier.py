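"""Hierarchical Bayesian estimation by differential-evolution MCMC.

Model structure (per task x condition cell, fit separately, as in the study
this package models): each subject's parameter vector, mapped to an
unconstrained scale by per-parameter transforms (log for scale-like
parameters, probit for probabilities, identity otherwise), is drawn from a
Normal(group location, group scale) per parameter; group locations get Normal
hyperpriors and group scales half-Normal hyperpriors, all on the transformed
scale.  Pooling across subjects is what lets 50-trial cells support stable
subject-level estimates.

Sampling is differential-evolution MCMC: many chains run in parallel and each
chain's proposal is its state plus gamma times the difference of two other
randomly chosen chains' states plus a small uniform jitter, with gamma =
2.38 / sqrt(2 d) — the inter-chain differences automatically adapt proposal
scale and orientation.  Subject blocks and the hyperparameter block alternate
(Gibbs-style); during burn-in only, a migration move occasionally permutes
states among a random subset of chains to free stuck chains.  Defaults mirror
the study: 33 chains, 120 retained iterations per chain after a 500-iteration
burn-in, 5% migration probability.

Convergence diagnostics: the Gelman-Rubin potential scale reduction factor
(between/within chain variance) and an autocorrelation-based effective sample
size (Geyer initial-positive-sequence truncation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "ParamDef",
    "SamplerConfig",
    "PosteriorChains",
    "de_mcmc_step",
    "de_mcmc_sample",
    "fit_hierarchical",
    "gelman_rubin",
    "effective_sample_size",
    "posterior_summary",
    "group_posterior_means",
    "RaceModelSpec",
    "DDMModelSpec",
]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _to_natural(x, transform):
    if transform == "identity":
        return x
    if transform == "log":
        return np.exp(x)
    if transform == "probit":
        return ndtr(x)
    raise ValueError(f"unknown transform {transform!r}")


def _to_transformed(x, transform):
    if transform == "identity":
        return x
    if transform == "log":
        return np.log(x)
    if transform == "probit":
        return ndtri(np.clip(x, 1e-12, 1 - 1e-12))
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class ParamDef:
    """One model parameter: its sampling transform, hyperpriors (on the
    transformed scale), and how it is reported (natural scale x
    ``report_scale``; probabilities use 100 to print as percent)."""

    name: str
    transform: str
    loc_prior: tuple          # (mean, sd) Normal hyperprior on group location
    scale_prior: float        # sd of half-Normal hyperprior on group scale
    report_scale: float = 1.0
    unit: str = ""


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 33
    n_burn: int = 500
    n_keep: int = 120
    thin: int = 5             # sweeps between stored draws after burn-in
    migration_prob: float = 0.05
    jitter: float = 1e-4      # uniform proposal jitter half-width scale

    def __post_init__(self) -> None:
        if self.n_chains < 3:
            raise ValueError("DE crossover needs at least 3 chains")


# ---------------------------------------------------------------------------
# core DE-MCMC step
# ---------------------------------------------------------------------------

def _pick_donors(n_chains: int, rng: np.random.Generator):
    """Per chain, two distinct donor chains, both different from the chain."""
    i = np.arange(n_chains)
    o1 = 1 + rng.integers(0, n_chains - 1, size=n_chains)
    o2 = 1 + rng.integers(0, n_chains - 2, size=n_chains)
    o2 = o2 + (o2 >= o1)
    return (i + o1) % n_chains, (i + o2) % n_chains


def de_mcmc_step(states, logp, logp_fn, rng, gamma: Optional[float] = None,
                 jitter: float = 1e-4, jitter_scale=None):
    """One DE-MCMC sweep over all chains.

    ``states`` is (C, d); ``logp`` the current log target per chain;
    ``logp_fn`` maps an (C, d) array of proposals to (C,) log targets.
    Proposal: x_i + gamma (x_r1 - x_r2) + eps, eps ~ U(-b, b) per dimension
    with b = jitter * jitter_scale (default 1).  Metropolis accept/reject.
    Returns (states, logp, accepted mask); inputs are not mutated.
    """
    states = np.asarray(states, dtype=float)
    n_chains, d = states.shape
    if gamma is None:
        gamma = 2.38 / np.sqrt(2.0 * d)
    r1, r2 = _pick_donors(n_chains, rng)
    b = jitter * (np.ones(d) if jitter_scale is None
                  else np.asarray(jitter_scale, dtype=float))
    eps = rng.uniform(-1.0, 1.0, size=states.shape) * b
    prop = states + gamma * (states[r1] - states[r2]) + eps
    logp_new = logp_fn(prop)
    with np.errstate(invalid="ignore"):
        accept = np.log(rng.random(n_chains)) < (logp_new - logp)
    accept &= np.isfinite(logp_new)
    out = np.where(accept[:, None], prop, states)
    lp = np.where(accept, logp_new, logp)
    return out, lp, accept


def de_mcmc_sample(logp_fn: Callable, init, n_steps: int, rng,
                   gamma: Optional[float] = None, jitter: float = 1e-4):
    """Plain (non-hierarchical) DE-MCMC run from ``init`` (C, d); returns
    samples (C, n_steps, d).  Used for known-target validation."""
    states = np.array(init, dtype=float)
    n_chains, d = states.shape
    logp = logp_fn(states)
    out = np.empty((n_chains, n_steps, d))
    for t in range(n_steps):
        states, logp, _ = de_mcmc_step(states, logp, logp_fn, rng,
                                       gamma=gamma, jitter=jitter)
        out[:, t, :] = states
    return out


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

class RaceModelSpec:
    """Hierarchical ex-Gaussian race with trigger and go failures: 8 subject
    parameters (go mu/sigma/tau, stop mu/sigma/tau, tf, gf)."""

    def __init__(self, max_rt: float = 1200.0):
        self.max_rt = max_rt
        self.params = (
            ParamDef("mu_go", "identity", (400.0, 300.0), 100.0, unit="ms"),
            ParamDef("sigma_go", "log", (np.log(50.0), 1.5), 0.5, unit="ms"),
            ParamDef("tau_go", "log", (np.log(80.0), 1.5), 0.5, unit="ms"),
            ParamDef("mu_stop", "identity", (200.0, 150.0), 50.0, unit="ms"),
            ParamDef("sigma_stop", "log", (np.log(40.0), 1.5), 0.5, unit="ms"),
            ParamDef("tau_stop", "log", (np.log(50.0), 1.5), 0.5, unit="ms"),
            ParamDef("tf", "probit", (-1.6, 1.0), 0.5, report_scale=100.0,
                     unit="%"),
            ParamDef("gf", "probit", (-2.5, 1.0), 0.5, report_scale=100.0,
                     unit="%"),
        )

    def compile_data(self, records):
        from .race import RaceData
        if isinstance(records, RaceData):
            return records
        return RaceData.from_records(records, max_rt=self.max_rt)

    def loglik(self, theta_nat, data):
        from .race import race_loglik_chains
        return race_loglik_chains(theta_nat, data)

    def init_center(self, data):
        """Method-of-moments start on the transformed scale."""
        rt = data.go_rt
        m = float(np.mean(rt)) if len(rt) else 450.0
        sd = float(np.std(rt)) if len(rt) > 1 else 100.0
        tau0 = max(0.6 * sd, 10.0)
        sig0 = max(np.sqrt(max(sd**2 - tau0**2, (0.25 * sd) ** 2)), 10.0)
        n_resp_go = len(rt) + data.n_go_omit
        gf0 = min(max(data.n_go_omit / max(n_resp_go, 1), 0.002), 0.5)
        return np.array([
            m - tau0, np.log(sig0), np.log(tau0),
            130.0, np.log(40.0), np.log(50.0),
            ndtri(0.03), ndtri(gf0),
        ])

    init_spread = property(lambda self: np.array(
        [30.0, 0.3, 0.3, 30.0, 0.4, 0.4, 0.8, 0.5]))
    #: update blocks: go-side (mu/sigma/tau go + gf) and stop-side
    #: (mu/sigma/tau stop + tf) — smaller proposals traverse the stop-side
    #: likelihood ridge far faster than joint 8-d moves
    blocks = ((0, 1, 2, 7), (3, 4, 5, 6))


class DDMModelSpec:
    """Hierarchical four-parameter diffusion of the Go subtask plus a
    go-failure probability: a, v, t0 (ms), z, gf."""

    def __init__(self, max_rt: float = 1200.0, coding: str = "accuracy"):
        self.max_rt = max_rt
        self.coding = coding
        self.params = (
            ParamDef("a", "log", (np.log(1.5), 1.0), 0.5, unit="a.u."),
            ParamDef("v", "identity", (2.0, 3.0), 1.0, unit="a.u."),
            ParamDef("t0", "log", (np.log(200.0), 1.0), 0.3, unit="ms"),
            ParamDef("z", "probit", (0.0, 0.5), 0.3, unit="a.u."),
            ParamDef("gf", "probit", (-2.5, 1.0), 0.5, report_scale=100.0,
                     unit="%"),
        )

    def compile_data(self, records):
        from .ddm import DDMData
        if isinstance(records, DDMData):
            return records
        return DDMData.from_records(records, max_rt=self.max_rt,
                                    coding=self.coding)

    def loglik(self, theta_nat, data):
        from .ddm import ddm_loglik_chains
        return ddm_loglik_chains(theta_nat, data)

    def init_center(self, data):
        from .ddm import ez_diffusion
        rts = np.concatenate([data.upper_rt, data.lower_rt])
        n = len(rts)
        if n < 5:
            return np.array([np.log(1.5), 2.0, np.log(200.0), 0.0,
                             ndtri(0.01)])
        p = len(data.upper_rt) / n
        a0, v0, t00 = ez_diffusion(p, float(np.mean(data.upper_rt)),
                                   float(np.var(data.upper_rt)), n=n)
        a0 = min(max(a0, 0.3), 5.0)
        v0 = min(max(v0, -8.0), 8.0)
        t00 = min(max(t00, 30.0), 0.9 * float(np.min(rts)))
        gf0 = min(max(data.n_omit / max(data.n_trials, 1), 0.002), 0.5)
        return np.array([np.log(a0), v0, np.log(t00), 0.0, ndtri(gf0)])

    init_spread = property(lambda self: np.array(
        [0.2, 0.5, 0.1, 0.2, 0.3]))
    blocks = ((0, 1, 2), (3, 4))


# ---------------------------------------------------------------------------
# hierarchical sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChains:
    """Retained DE-MCMC draws: subject-level samples (chain, iteration,
    subject, parameter) and group-level location/scale (chain, iteration,
    parameter), all on the transformed scale, plus diagnostics."""

    subj: np.ndarray
    hyper_loc: np.ndarray
    hyper_scale: np.ndarray
    param_names: tuple
    transforms: tuple
    report_scales: tuple
    units: tuple
    n_burn: int
    accept_rate: float

    @property
    def n_chains(self) -> int:
        return self.subj.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.subj.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subj.shape[2]

    def subject_natural(self) -> np.ndarray:
        """Subject-level samples mapped to the natural scale."""
        out = np.empty_like(self.subj)
        for j, tr in enumerate(self.transforms):
            out[..., j] = _to_natural(self.subj[..., j], tr)
        return out

    def rhat(self) -> dict:
        """Gelman-Rubin R-hat of the group-location chains per parameter."""
        return {name: gelman_rubin(self.hyper_loc[:, :, j])
                for j, name in enumerate(self.param_names)}

    def ess(self) -> dict:
        """Effective sample size of the group-location chains per parameter."""
        return {name: effective_sample_size(self.hyper_loc[:, :, j])
                for j, name in enumerate(self.param_names)}


def _hyper_cond_logp(subj_j, loc, logscale, loc_mean, loc_sd, scale_sd):
    """Conditional log-posterior of one parameter's (group location, group
    log-scale) given the subject values ``subj_j`` (C, S): Normal
    subject-level terms + Normal hyperprior on the location + half-Normal on
    the scale with the log-transform Jacobian."""
    scale = np.exp(logscale)
    n_subj = subj_j.shape[1]
    z = (subj_j - loc[:, None]) / scale[:, None]
    lp = -0.5 * (z**2).sum(axis=1) - n_subj * logscale
    lp += -0.5 * ((loc - loc_mean) / loc_sd) ** 2
    lp += -0.5 * (scale / scale_sd) ** 2 + logscale
    return lp


def fit_hierarchical(records_by_subject: Sequence, model,
                     config: SamplerConfig = SamplerConfig(),
                     seed=0) -> PosteriorChains:
    """Fit the hierarchical model to one cell's data (one entry per subject:
    trial records or a pre-compiled data object).  Reproducible per seed."""
    rng = np.random.default_rng(seed)
    datas = [model.compile_data(r) for r in records_by_subject]
    S = len(datas)
    names = tuple(p.name for p in model.params)
    transforms = tuple(p.transform for p in model.params)
    d = len(names)
    C = config.n_chains

    loc_mean = np.array([p.loc_prior[0] for p in model.params])
    loc_sd = np.array([p.loc_prior[1] for p in model.params])
    scale_sd = np.array([p.scale_prior for p in model.params])
    spread = model.init_spread

    def nat(theta):
        out = np.empty_like(theta)
        for j, tr in enumerate(transforms):
            out[..., j] = _to_natural(theta[..., j], tr)
        return out

    # --- initialization: moments-based centers, jittered per chain ---------
    centers = np.stack([model.init_center(dat) for dat in datas])   # (S, d)
    subj = centers[None, :, :] + rng.normal(
        0.0, 1.0, size=(C, S, d)) * (0.5 * spread)[None, None, :]
    data_ll = np.stack(
        [model.loglik(nat(subj[:, s, :]), datas[s]) for s in range(S)],
        axis=1)                                                     # (C, S)
    for _ in range(200):
        bad = ~np.isfinite(data_ll)
        if not bad.any():
            break
        ci, si = np.nonzero(bad)
        subj[ci, si, :] = centers[si] + rng.normal(
            0.0, 1.0, size=(len(ci), d)) * (0.25 * spread)[None, :]
        for s in np.unique(si):
            rows = ci[si == s]
            data_ll[rows, s] = model.loglik(nat(subj[rows, s, :]), datas[s])
    else:
        raise RuntimeError(
            "could not find finite-likelihood start values; check the data "
            "against the model's support")

    hloc = centers.mean(axis=0)[None, :] + rng.normal(
        0.0, 1.0, size=(C, d)) * (0.3 * spread)[None, :]
    hlogscale = np.log(np.maximum(spread, 1e-3))[None, :] + rng.normal(
        0.0, 0.2, size=(C, d))

    gamma_s = 2.38 / np.sqrt(2.0 * d)
    gamma_h = 2.38 / np.sqrt(2.0 * 2)      # 2-d (location, log-scale) blocks
    block_idx = [np.asarray(b, dtype=int)
                 for b in getattr(model, "blocks", [tuple(range(d))])]
    block_gammas = [2.38 / np.sqrt(2.0 * len(b)) for b in block_idx]
    jit_s = config.jitter * np.maximum(spread, 1e-3)
    jit_h2 = config.jitter * np.column_stack(
        [np.maximum(spread, 1e-3), np.full(d, 0.1)])

    n_total = config.n_burn + config.n_keep * config.thin
    keep_subj = np.empty((C, config.n_keep, S, d))
    keep_loc = np.empty((C, config.n_keep, d))
    keep_scale = np.empty((C, config.n_keep, d))
    n_acc = 0
    n_prop = 0

    for it in range(n_total):
        # migration (burn-in only): permute a random subset of chains
        if it < config.n_burn and rng.random() < config.migration_prob:
            k = rng.integers(2, max(C // 2, 3))
            sel = rng.choice(C, size=k, replace=False)
            perm = np.roll(sel, 1)
            subj[sel] = subj[perm]
            data_ll[sel] = data_ll[perm]
            hloc[sel] = hloc[perm]
            hlogscale[sel] = hlogscale[perm]

        # subject updates, one DE block at a time (gamma = 2.38/sqrt(2 d_b))
        hscale = np.exp(hlogscale)
        for s in range(S):
            for blk, gmb in zip(block_idx, block_gammas):
                x = subj[:, s, :]
                prop = x.copy()
                if rng.random() < 0.15:
                    # independence proposal from the subject-level prior for
                    # this block: the block's prior terms cancel against the
                    # proposal density, leaving the data-likelihood ratio.
                    # DE differences collapse when every chain sits on the
                    # same submanifold; this move restores diversity there.
                    prop[:, blk] = (hloc[:, blk] + hscale[:, blk]
                                    * rng.standard_normal((C, len(blk))))
                    ll_new = model.loglik(nat(prop), datas[s])
                    with np.errstate(invalid="ignore"):
                        acc = np.log(rng.random(C)) < (ll_new
                                                       - data_ll[:, s])
                else:
                    r1, r2 = _pick_donors(C, rng)
                    eps = rng.uniform(-1.0, 1.0,
                                      size=(C, len(blk))) * jit_s[blk]
                    prop[:, blk] = (x[:, blk]
                                    + gmb * (x[r1][:, blk] - x[r2][:, blk])
                                    + eps)
                    ll_new = model.loglik(nat(prop), datas[s])
                    zp = (prop - hloc) / hscale
                    pr_new = (-0.5 * zp**2 - hlogscale).sum(axis=1)
                    cur = data_ll[:, s] + (
                        -0.5 * ((x - hloc) / hscale) ** 2
                        - hlogscale).sum(axis=1)
                    with np.errstate(invalid="ignore"):
                        acc = np.log(rng.random(C)) < (ll_new + pr_new - cur)
                acc &= np.isfinite(ll_new)
                subj[acc, s, :] = prop[acc]
                data_ll[acc, s] = ll_new[acc]
                n_acc += int(acc.sum())
                n_prop += C

        # hyper blocks: the prior factorizes over parameters, so each
        # (location_j, log-scale_j) pair is its own cheap 2-d DE block;
        # several repeats per sweep speed the subject/hyper coupling along
        for _ in range(3):
            for j in range(d):
                x = np.column_stack([hloc[:, j], hlogscale[:, j]])
                r1, r2 = _pick_donors(C, rng)
                eps = rng.uniform(-1.0, 1.0, size=x.shape) * jit_h2[j]
                prop = x + gamma_h * (x[r1] - x[r2]) + eps
                new = _hyper_cond_logp(subj[:, :, j], prop[:, 0], prop[:, 1],
                                       loc_mean[j], loc_sd[j], scale_sd[j])
                cur = _hyper_cond_logp(subj[:, :, j], hloc[:, j],
                                       hlogscale[:, j], loc_mean[j],
                                       loc_sd[j], scale_sd[j])
                with np.errstate(invalid="ignore"):
                    acc = np.log(rng.random(C)) < (new - cur)
                acc &= np.isfinite(new)
                hloc[acc, j] = prop[acc, 0]
                hlogscale[acc, j] = prop[acc, 1]
                n_acc += int(acc.sum())
                n_prop += C

        # group-shift move: translate the group location and every subject's
        # value together (the subject-level prior terms are invariant, so the
        # ratio involves only data likelihoods and the location hyperprior).
        # This decouples the slow location/subject random walk of the
        # centered hierarchy and is what lets short runs mix.
        for blk, gmb in zip(block_idx, block_gammas):
            r1, r2 = _pick_donors(C, rng)
            delta = np.zeros((C, d))
            delta[:, blk] = (gmb * (hloc[r1][:, blk] - hloc[r2][:, blk])
                             + rng.uniform(-1.0, 1.0, size=(C, len(blk)))
                             * jit_s[blk])
            ploc = hloc + delta
            psubj = subj + delta[:, None, :]
            ll_new = np.stack(
                [model.loglik(nat(psubj[:, s, :]), datas[s])
                 for s in range(S)], axis=1)
            dlp = ll_new.sum(axis=1) - data_ll.sum(axis=1)
            dlp += -0.5 * ((((ploc - loc_mean) / loc_sd) ** 2)
                           - (((hloc - loc_mean) / loc_sd) ** 2)).sum(axis=1)
            with np.errstate(invalid="ignore"):
                acc = np.log(rng.random(C)) < dlp
            acc &= np.isfinite(ll_new.sum(axis=1))
            subj[acc] = psubj[acc]
            hloc[acc] = ploc[acc]
            data_ll[acc] = ll_new[acc]
            n_acc += int(acc.sum())
            n_prop += C

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            j = (it - config.n_burn) // config.thin
            keep_subj[:, j] = subj
            keep_loc[:, j] = hloc
            keep_scale[:, j] = np.exp(hlogscale)

    if np.allclose(keep_subj.std(axis=(0, 1)), 0.0):
        raise RuntimeError("all chains collapsed to a single state")

    return PosteriorChains(
        subj=keep_subj,
        hyper_loc=keep_loc,
        hyper_scale=keep_scale,
        param_names=names,
        transforms=transforms,
        report_scales=tuple(p.report_scale for p in model.params),
        units=tuple(p.unit for p in model.params),
        n_burn=config.n_burn,
        accept_rate=n_acc / max(n_prop, 1),
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar quantity.

    ``chains`` is (m, n): m chains of n retained iterations.  Returns NaN
    (undefined) when the within-chain variance is zero — never a spurious 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 iterations")
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return float("nan")
    b_over_n = x.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def effective_sample_size(chains) -> float:
    """Autocorrelation-adjusted ESS: m*n / (1 + 2 sum rho_t), with the
    autocorrelation sum truncated by Geyer's initial positive-pair rule;
    chain-averaged autocovariances.  NaN for constant chains."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 iterations")
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    c = acov.mean(axis=0)
    if c[0] <= 0.0:
        return float("nan")
    rho = c / c[0]
    # Geyer: sum consecutive pairs while their sum stays positive
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        total += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * total)
    return float(min(ess, m * n))


def group_posterior_means(chains: PosteriorChains) -> dict:
    """Across-subject mean of subject-level posterior means on the reporting
    scale (ms / % / a.u.) — comparable to printed group descriptive rows."""
    nat = chains.subject_natural()                 # (C, T, S, d)
    out = {}
    for j, name in enumerate(chains.param_names):
        out[name] = float(nat[..., j].mean() * chains.report_scales[j])
    return out


def posterior_summary(chains: PosteriorChains, rhat_threshold: float = 1.1,
                      allow_unconverged: bool = False) -> pd.DataFrame:
    """Per-parameter posterior summary on the reporting scale: group mean
    (across-subject mean of subject posterior means), posterior SD of that
    group mean, central 95% interval, between-subject SD of subject posterior
    means, R-hat and ESS of the group-location chains.

    Raises unless every R-hat is below ``rhat_threshold`` (or the override is
    set): summarizing unconverged chains silently is how wrong tables happen.
    """
    rh = chains.rhat()
    bad = {k: v for k, v in rh.items()
           if np.isfinite(v) and v >= rhat_threshold}
    if bad and not allow_unconverged:
        raise RuntimeError(
            f"unconverged chains (R-hat >= {rhat_threshold}): {bad}; "
            "pass allow_unconverged=True to summarize anyway")
    ess = chains.ess()
    nat = chains.subject_natural()
    rows = []
    for j, name in enumerate(chains.param_names):
        scale = chains.report_scales[j]
        grp = nat[..., j].mean(axis=2) * scale          # (C, T) group mean
        subj_means = nat[..., j].mean(axis=(0, 1)) * scale
        rows.append({
            "parameter": name,
            "unit": chains.units[j],
            "mean": float(grp.mean()),
            "sd": float(grp.std(ddof=1)),
            "ci2.5": float(np.quantile(grp, 0.025)),
            "ci97.5": float(np.quantile(grp, 0.975)),
            "between_subject_sd": float(np.std(subj_means, ddof=1)),
            "rhat": rh[name],
            "ess": ess[name],
        })
    return pd.DataFrame(rows)
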