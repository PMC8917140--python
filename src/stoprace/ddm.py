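"""Wiener first-passage-time density and the Go-subtask likelihood.

The decision process is a one-dimensional diffusion between absorbing
boundaries 0 and ``a`` starting at ``z * a`` with drift ``v`` and unit
within-trial noise.  The first-passage density at the lower boundary for
decision time ``t`` (seconds) factorizes as

    f_lower(t | v, a, w) = (1 / a^2) * exp(-v a w - v^2 t / 2) * f1(t / a^2, w)

with w = z and f1 the standardized density, available as two series
expansions — one converging fast for small scaled time, one for large scaled
time:

    small:  f1(u, w) = (2 pi u^3)^(-1/2) * sum_k (w + 2k) exp(-(w + 2k)^2 / 2u)
    large:  f1(u, w) = pi * sum_{k>=1} k exp(-k^2 pi^2 u / 2) sin(k pi w)

Each evaluation picks the series whose truncation bound reaches the error
budget (1e-7 per density value) with fewer terms.  The upper-boundary density
is the lower-boundary density under (v, w) -> (-v, 1 - w).

Response-rule convention (accuracy coding, the default): correct responses
absorb at the upper boundary, errors at the lower.  Response coding (left =
upper) is available via the ``coding`` switch on the likelihood; the data then
need a response-side column rather than a correctness flag.

API times are ms; internal computation is in seconds (s = 1 noise).
"""

from __future__ import annotations

import warnings

import numpy as np

from .generative import (
    DDM_TIME_CAP_S,
    DDMParams,
    ddm_upper_probability,
    simulate_ddm_trials,
)

__all__ = [
    "wiener_fpt_density",
    "wiener_logpdf",
    "decision_survival",
    "loglik_go_trial",
    "fit_ddm_summary",
    "ez_diffusion",
    "DDMData",
    "ddm_loglik_chains",
]

_ERR = 1e-7          # truncation budget per density evaluation
_KMAX = 120          # series-length guard


def _f1_standardized(u, w):
    """Standardized lower-boundary density f1(u, w), vectorized; u > 0."""
    u = np.asarray(u, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape)
    out = np.zeros_like(u)
    pos = u > 0
    if not pos.any():
        return out
    uu, ww = u[pos], w[pos]

    # terms needed (Navarro & Fuss 2009 bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * uu) * _ERR
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * uu * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(uu) + 1.0)
        arg_l = np.pi * uu * _ERR
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * uu)),
            1.0 / (np.pi * np.sqrt(uu)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(uu)))

    use_small = ks < kl
    res = np.empty_like(uu)

    if use_small.any():
        us, ws = uu[use_small], ww[use_small]
        K = int(np.ceil(ks[use_small].max()))
        if K > _KMAX:
            raise FloatingPointError(
                f"small-time series needs {K} terms (> {_KMAX})")
        k = np.arange(-K, K + 1, dtype=float)
        wk = ws[:, None] + 2.0 * k[None, :]
        terms = wk * np.exp(-(wk**2) / (2.0 * us[:, None]))
        res[use_small] = terms.sum(axis=1) / np.sqrt(
            2.0 * np.pi * us**3)

    if (~use_small).any():
        ul, wl = uu[~use_small], ww[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        if K > _KMAX:
            raise FloatingPointError(
                f"large-time series needs {K} terms (> {_KMAX})")
        k = np.arange(1, K + 1, dtype=float)
        terms = (k[None, :]
                 * np.exp(-(k[None, :]**2) * np.pi**2 * ul[:, None] / 2.0)
                 * np.sin(k[None, :] * np.pi * wl[:, None]))
        res[~use_small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(res, 0.0)
    return out


def wiener_logpdf(t_s, a, v, w, boundary: str = "lower"):
    """Log first-passage density (per second) at decision time ``t_s``
    seconds; -inf at t_s <= 0.  Vectorized over ``t_s``/params jointly."""
    t_s = np.asarray(t_s, dtype=float)
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if boundary == "upper":
        v, w = -v, 1.0 - w
    elif boundary != "lower":
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary}")
    t_s, a, v, w = np.broadcast_arrays(t_s, a, v, w)
    u = np.where(t_s > 0, t_s, np.nan) / a**2
    f1 = _f1_standardized(np.where(np.isnan(u), 0.0, u), w)
    with np.errstate(divide="ignore"):
        out = (-2.0 * np.log(a) - v * a * w - v**2 * t_s / 2.0
               + np.log(f1))
    return np.where(t_s > 0, out, -np.inf)


def wiener_fpt_density(t_ms, boundary: str, params: DDMParams):
    """First-passage density per ms at decision time ``t_ms`` (already net of
    non-decision time)."""
    t_s = np.asarray(t_ms, dtype=float) / 1000.0
    lp = wiener_logpdf(t_s, params.a, params.v, params.z, boundary=boundary)
    return np.exp(lp) / 1000.0


# 96 nodes hold ~1e-13 on the defective-density CDF across the parameter
# ranges of interest (validated against 512-node GL)
_SURV_NODES = 96
_sx, _sw = np.polynomial.legendre.leggauss(_SURV_NODES)


def decision_survival(u0_s, a, v, w):
    """P(decision time > u0_s), either boundary, by Gauss-Legendre quadrature
    of both defective densities on [0, u0_s].  Vectorized over chains (a, v, w
    arrays of shape (C,); u0_s array of shape (C,) or scalar).  Horizons
    beyond the 20 s censoring cap are evaluated at the cap — the mass beyond
    it is negligible for any parameters of interest, and an unbounded
    interval would starve the fixed quadrature of resolution."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    u0 = np.broadcast_to(np.asarray(u0_s, dtype=float), a.shape)
    u0 = np.minimum(u0, DDM_TIME_CAP_S)
    out = np.ones_like(u0)
    pos = u0 > 0
    if not pos.any():
        return out
    mid = 0.5 * u0[pos]
    t = mid[:, None] * (1.0 + _sx[None, :])          # (C, K)
    wq = mid[:, None] * _sw[None, :]
    dens = np.zeros_like(t)
    for b in ("lower", "upper"):
        dens += np.exp(wiener_logpdf(
            t, a[pos][:, None], v[pos][:, None], w[pos][:, None], boundary=b))
    cdf = (dens * wq).sum(axis=1)
    out[pos] = np.clip(1.0 - cdf, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Go-subtask likelihood
# ---------------------------------------------------------------------------

def loglik_go_trial(correct, rt_ms, params: DDMParams, gf: float = 0.0,
                    max_rt: float = 1200.0, coding: str = "accuracy") -> float:
    """Log-likelihood of one go trial under the diffusion + go-failure model.

    ``rt_ms=None`` marks an omission: log[gf + (1-gf) P(decision time >
    max_rt - t0)].  For responded trials with ``coding='accuracy'`` a correct
    response maps to the upper boundary; with ``coding='response'`` the
    ``correct`` argument is instead interpreted as "responded left" -> upper.
    A responded trial with rt <= t0 has zero likelihood: -inf with a warning.
    """
    if coding not in ("accuracy", "response"):
        raise ValueError(f"unknown coding {coding!r}")
    if rt_ms is None:
        u0 = (max_rt - params.t0) / 1000.0
        surv = float(decision_survival(u0, params.a, params.v, params.z)[0])
        with np.errstate(divide="ignore"):
            return float(np.log(gf + (1.0 - gf) * surv))
    t_dec = rt_ms - params.t0
    if t_dec <= 0:
        warnings.warn(
            f"responded trial rt={rt_ms} <= t0={params.t0}: zero likelihood",
            RuntimeWarning, stacklevel=2)
        return -np.inf
    boundary = "upper" if correct else "lower"
    lp = float(wiener_logpdf(t_dec / 1000.0, params.a, params.v, params.z,
                             boundary=boundary)) - np.log(1000.0)
    with np.errstate(divide="ignore"):
        return float(np.log1p(-gf)) + lp


def fit_ddm_summary(params: DDMParams, n: int = 100_000,
                    rng: np.random.Generator | None = None,
                    dt_ms: float = 0.1):
    """Posterior-predictive style summaries from fitted parameters by
    simulation: (p_correct, mean correct RT ms, mean error RT ms); an
    undefined sub-mean is returned as NaN."""
    rng = np.random.default_rng() if rng is None else rng
    b, rt, cens = simulate_ddm_trials(params, n, rng, dt_ms=dt_ms)
    ok = ~cens
    up = (b == 1) & ok
    lo = (b == -1) & ok
    p_correct = up.sum() / max(ok.sum(), 1)
    mean_c = float(rt[up].mean()) if up.any() else float("nan")
    mean_e = float(rt[lo].mean()) if lo.any() else float("nan")
    return float(p_correct), mean_c, mean_e


def ez_diffusion(p_correct: float, mean_rt_ms: float, var_rt_ms2: float,
                 n: int | None = None):
    """Closed-form moment estimator of (a, v, t0) from accuracy, correct-RT
    mean and variance — used to initialize samplers.  Edge-corrects p in
    {0, .5, 1} when ``n`` is given (else nudges by 1e-4)."""
    p = float(p_correct)
    eps = 1.0 / (2.0 * n) if n else 1e-4
    p = min(max(p, eps), 1.0 - eps)
    if abs(p - 0.5) < eps:
        p = 0.5 + eps
    vrt = max(var_rt_ms2, 1e-6) / 1e6          # s^2
    mrt = mean_rt_ms / 1e3                     # s
    L = np.log(p / (1.0 - p))
    x = L * (L * p**2 - L * p + p - 0.5) / vrt
    v = np.sign(p - 0.5) * x**0.25
    a = L / v
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    t0 = max(mrt - mdt, 1e-3)
    return float(a), float(v), float(t0 * 1000.0)


# ---------------------------------------------------------------------------
# chain-vectorized dataset likelihood (used by the hierarchical sampler)
# ---------------------------------------------------------------------------

class DDMData:
    """One subject-cell's go trials arranged for the diffusion likelihood:
    upper-boundary RTs, lower-boundary RTs and omission count."""

    def __init__(self, upper_rt, lower_rt, n_omit: int,
                 max_rt: float = 1200.0):
        self.upper_rt = np.asarray(upper_rt, dtype=float)
        self.lower_rt = np.asarray(lower_rt, dtype=float)
        self.n_omit = int(n_omit)
        self.max_rt = float(max_rt)

    @classmethod
    def from_records(cls, records, max_rt: float = 1200.0,
                     coding: str = "accuracy") -> "DDMData":
        """Compile go trials from TrialRecords or a trial-table DataFrame.
        Accuracy coding: correct -> upper; response coding: left -> upper."""
        import pandas as pd
        if isinstance(records, pd.DataFrame):
            rows = [
                (r.trial_type, r.response,
                 None if pd.isna(r.rt_ms) else float(r.rt_ms),
                 None if pd.isna(r.correct) else bool(r.correct))
                for r in records.itertuples(index=False)
            ]
        else:
            rows = [(r.trial_type, r.response, r.rt, r.correct)
                    for r in records]
        upper, lower = [], []
        n_omit = 0
        for trial_type, response, rt, correct in rows:
            if trial_type != "go":
                continue
            if response == "none" or rt is None:
                n_omit += 1
                continue
            to_upper = correct if coding == "accuracy" else (response == "left")
            (upper if to_upper else lower).append(rt)
        return cls(upper, lower, n_omit, max_rt=max_rt)

    @property
    def n_trials(self) -> int:
        return len(self.upper_rt) + len(self.lower_rt) + self.n_omit


def ddm_loglik_chains(theta, data: DDMData):
    """Total go-subtask log-likelihood per chain.

    ``theta`` is (C, 5) natural-scale: columns a, v, t0 (ms), z, gf.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    a, v, t0, z, gf = (theta[:, i] for i in range(5))
    ll = np.zeros(theta.shape[0])
    with np.errstate(divide="ignore"):
        lg = np.log1p(-gf)
    for rts, boundary in ((data.upper_rt, "upper"), (data.lower_rt, "lower")):
        if not len(rts):
            continue
        t_dec = (rts[None, :] - t0[:, None]) / 1000.0
        lp = wiener_logpdf(t_dec, a[:, None], v[:, None], z[:, None],
                           boundary=boundary) - np.log(1000.0)
        ll += lp.sum(axis=1) + len(rts) * lg
    if data.n_omit:
        u0 = (data.max_rt - t0) / 1000.0
        surv = decision_survival(u0, a, v, z)
        with np.errstate(divide="ignore"):
            ll += data.n_omit * np.log(gf + (1.0 - gf) * surv)
    return ll
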