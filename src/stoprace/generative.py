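"""Building-block samplers and densities for stop-signal modelling.

Three generative primitives live here:

* the ex-Gaussian distribution (Normal(mu, sigma) + Exponential(tau)), the
  conventional description of both go-RT and stop-latency (SSRT) distributions;
* the independent horse race between a go and a stop process, extended with a
  trigger-failure probability ``tf`` (the stop process is never launched) and a
  go-failure probability ``gf`` (omission of the go response);
* the two-boundary diffusion (drift ``v``, boundary separation ``a``, relative
  start point ``z``, non-decision time ``t0``) of the Go decision.

All times are milliseconds at the API boundary.  The diffusion simulator works
in seconds internally because the within-trial noise convention is s = 1 per
sqrt(second).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "ExGaussParams",
    "RaceParams",
    "DDMParams",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_cdf",
    "exgauss_survival",
    "sample_exgauss",
    "simulate_race_trial",
    "simulate_race_trials",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "ddm_upper_probability",
]

#: hard cap on simulated decision time, seconds; longer paths are censored
DDM_TIME_CAP_S = 20.0


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian parameters in ms: mean mu + SD sigma of the Gaussian
    component, mean tau of the exponential component."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


@dataclass(frozen=True)
class RaceParams:
    """Horse-race parameters: go and stop ex-Gaussians plus the trigger-failure
    probability ``tf``, the go-failure probability ``gf``, and the response
    deadline ``max_rt`` (ms)."""

    go: ExGaussParams
    stop: ExGaussParams
    tf: float = 0.0
    gf: float = 0.0
    max_rt: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("tf", "gf"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not (self.max_rt > 0):
            raise ValueError(f"max_rt must be > 0, got {self.max_rt}")


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters: boundary separation ``a`` (a.u.), drift ``v``
    (evidence/s), non-decision time ``t0`` (ms), relative start point ``z`` in
    (0, 1); within-trial noise fixed at s = 1."""

    a: float
    v: float
    t0: float
    z: float = 0.5
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"z must be in (0, 1), got {self.z}")
        if not (self.t0 >= 0):
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.s != 1.0:
            raise ValueError("within-trial noise is fixed at s = 1")


# ---------------------------------------------------------------------------
# ex-Gaussian
# ---------------------------------------------------------------------------

def exgauss_logpdf(t, mu, sigma, tau):
    """Log density of the ex-Gaussian at ``t`` (ms), vectorized.

    log f(t) = -log tau + sigma^2/(2 tau^2) - (t - mu)/tau
               + log Phi((t - mu)/sigma - sigma/tau)

    computed fully in log space so that small-``tau``/large-``sigma`` corners
    do not overflow.
    """
    t = np.asarray(t, dtype=float)
    mu, sigma, tau = (np.asarray(x, dtype=float) for x in (mu, sigma, tau))
    u = (t - mu) / sigma
    return (
        -np.log(tau)
        + sigma**2 / (2.0 * tau**2)
        - (t - mu) / tau
        + log_ndtr(u - sigma / tau)
    )


def exgauss_pdf(t, params: ExGaussParams):
    """Ex-Gaussian density per ms at ``t``."""
    return np.exp(exgauss_logpdf(t, params.mu, params.sigma, params.tau))


def exgauss_cdf(t, mu, sigma, tau):
    """Ex-Gaussian CDF, vectorized: Phi(u) - exp(log-space correction term)."""
    return 1.0 - exgauss_survival(t, mu, sigma, tau)


def exgauss_survival(t, mu, sigma, tau):
    """P(T > t), computed as Phi(-u) + exp(c) with the correction term c kept
    in log space (stable where exp(sigma^2 / 2 tau^2) alone would overflow)."""
    t = np.asarray(t, dtype=float)
    mu, sigma, tau = (np.asarray(x, dtype=float) for x in (mu, sigma, tau))
    u = (t - mu) / sigma
    c = sigma**2 / (2.0 * tau**2) - (t - mu) / tau + log_ndtr(u - sigma / tau)
    out = ndtr(-u) + np.exp(c)
    return np.clip(out, 0.0, 1.0)


def sample_exgauss(params: ExGaussParams, n: int, rng: np.random.Generator):
    """Draw ``n`` ex-Gaussian variates (ms) as Normal + Exponential."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return rng.normal(params.mu, params.sigma, size=n) + rng.exponential(
        params.tau, size=n
    )


# ---------------------------------------------------------------------------
# stop-signal race
# ---------------------------------------------------------------------------

def simulate_race_trials(params: RaceParams, ssd: float, n: int,
                         rng: np.random.Generator):
    """Simulate ``n`` stop trials of the race at stop-signal delay ``ssd``.

    Returns ``(outcome, rt)`` where ``outcome`` is an int array with codes
    0 = go omission / successful stop without go activity is not separated —
    see below — so the codes are: 0 = no response (observationally a
    successful stop, whatever its latent cause), 1 = signal-respond with
    ``rt`` (ms) valid.

    Latent logic per trial: with probability ``gf`` the go process never
    starts; otherwise a go RT is drawn.  With probability ``tf`` the stop
    process is never triggered, so a response occurs iff the go RT is within
    the deadline; otherwise a stop latency is drawn and the response occurs
    iff go RT < ssd + stop latency and go RT <= max_rt.
    """
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    go_rt = sample_exgauss(params.go, n, rng)
    # latencies are physically nonnegative; the likelihood truncates the
    # stop runner at 0 the same way
    stop_lat = np.maximum(sample_exgauss(params.stop, n, rng), 0.0)
    go_fails = rng.random(n) < params.gf
    trig_fails = rng.random(n) < params.tf
    within = (go_rt <= params.max_rt) & (go_rt > 0)
    beats_stop = trig_fails | (go_rt < ssd + stop_lat)
    respond = (~go_fails) & within & beats_stop
    outcome = respond.astype(int)
    rt = np.where(respond, go_rt, np.nan)
    return outcome, rt


def simulate_race_trial(params: RaceParams, ssd: float,
                        rng: np.random.Generator):
    """One race trial; returns ``('signal_respond', rt)`` or
    ``('inhibited', None)`` (no observable response; includes go omissions)."""
    outcome, rt = simulate_race_trials(params, ssd, 1, rng)
    if outcome[0] == 1:
        return "signal_respond", float(rt[0])
    return "inhibited", None


def simulate_go_trials(params: RaceParams, n: int, rng: np.random.Generator):
    """Simulate ``n`` go trials: returns rt array with NaN for omissions."""
    go_rt = sample_exgauss(params.go, n, rng)
    go_fails = rng.random(n) < params.gf
    ok = (~go_fails) & (go_rt <= params.max_rt) & (go_rt > 0)
    return np.where(ok, go_rt, np.nan)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def ddm_upper_probability(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary,
    (1 - exp(-2 v a z)) / (1 - exp(-2 v a)); tends to z as v -> 0."""
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-12:
        return z
    x = -2.0 * v * a
    return float(np.expm1(x * z) / np.expm1(x))


def simulate_ddm_trials(params: DDMParams, n: int, rng: np.random.Generator,
                        dt_ms: float = 0.1):
    """Euler–Maruyama simulation of ``n`` diffusion trials.

    Returns ``(boundary, rt_ms, censored)``: boundary +1 (upper) or -1
    (lower), rt in ms including ``t0``; paths still unabsorbed after 20 s of
    decision time are censored (flag set, boundary by the sign of the final
    position relative to ``z * a``).

    Within-step boundary crossings are detected by the Brownian-bridge
    probability exp(-2 (b - x0)(b - x1) / (s^2 dt)); without this the plain
    Euler scheme biases first-passage times upward by O(sqrt(dt)).
    """
    dt = dt_ms / 1000.0
    sqdt = np.sqrt(dt)
    a, v, z = params.a, params.v, params.z
    s2dt = params.s**2 * dt
    x = np.full(n, z * a)
    t_steps = np.zeros(n, dtype=np.int64)
    boundary = np.zeros(n, dtype=np.int8)
    active = np.ones(n, dtype=bool)
    max_steps = int(DDM_TIME_CAP_S / dt)
    step = 0
    idx = np.arange(n)
    while active.any() and step < max_steps:
        ia = idx[active]
        x_old = x[ia]
        x_new = x_old + v * dt + params.s * sqdt * rng.standard_normal(
            ia.size)
        step += 1
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        inside = ~(hit_up | hit_lo)
        if inside.any():
            xo, xn = x_old[inside], x_new[inside]
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * (a - xo) * (a - xn) / s2dt)
                p_lo = np.exp(-2.0 * xo * xn / s2dt)
            u = rng.random(xo.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hu, hl = hit_up.copy(), hit_lo.copy()
            hu[inside] = bridge_up
            hl[inside] = bridge_lo
            hit_up, hit_lo = hu, hl
        x[ia] = x_new
        done = hit_up | hit_lo
        if done.any():
            d = ia[done]
            boundary[d] = np.where(hit_up[done], 1, -1)
            t_steps[d] = step
            active[d] = False
        t_steps[ia[~done]] = step
    censored = active.copy()
    if censored.any():
        boundary[censored] = np.where(x[censored] >= z * a, 1, -1)
    rt_ms = t_steps * dt_ms + params.t0
    return boundary, rt_ms, censored


def simulate_ddm_trial(params: DDMParams, rng: np.random.Generator,
                       dt_ms: float = 0.1):
    """One diffusion trial; returns ``(boundary, rt_ms)`` with boundary in
    {'upper', 'lower'}; raises no error on censoring (flag folded into rt)."""
    b, rt, cens = simulate_ddm_trials(params, 1, rng, dt_ms=dt_ms)
    name = "upper" if b[0] == 1 else "lower"
    return name, float(rt[0])
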