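# Methods

## Scope and units

The package implements a complete analysis pipeline for two-task,
three-condition stop-signal experiments: task simulation, standard
behavioural measures, an ex-Gaussian race likelihood with failure mixtures, a
diffusion model of the Go subtask, hierarchical DE-MCMC estimation, and a
group-statistics layer.  Times are milliseconds at every API and file
boundary.  The diffusion computations run in seconds internally because the
within-trial noise convention is s = 1 per √second — the published magnitudes
(a ≈ 1.3–1.8, ν ≈ 1.3–4.2, t₀ ≈ 150–240 ms) are only consistent with that
convention, not with s = 0.1.  The ex-Gaussian race likelihood is computed in
ms throughout; its log-space forms are well conditioned there.

## Task engine

Sessions have exact composition: `n_trials · p_stop` stop trials, not a
Bernoulli draw.  The pseudo-randomization constraint (the design only says
"unpredictable") is: first two trials are go, and never more than three
consecutive stop trials.  Sequences are built constructively — stop trials
are assigned to the capacity-3 gaps following the 2nd…last go trial — so any
admissible composition can be generated, including the long tracking runs
used for staircase validation (rejection shuffling has vanishing acceptance
there).

The SSD staircase starts at 200 ms and moves ±75 ms (up after a successful
stop, down after a failed one).  No clamp rule is reported for the original
task; SSDs are clamped to [0, max_rt − step] here, since negative or
beyond-deadline delays are meaningless.  The staircase resets to 200 ms each
session (whether the original carried SSD across conditions is unstated).
Fixation (250 ms) and inter-trial interval (250 ms) are carried as metadata
only — they enter no likelihood.  Go-stimulus/response-side counterbalancing
is recorded but not modelled; it has no consequence in either likelihood.

Two generative agents drive simulated sessions: a pure race agent
(ex-Gaussian go RTs; responded go trials are scored correct, since the race
model has no accuracy component) and a hybrid agent whose Go decision is a
diffusion (accuracy + RT) racing the ex-Gaussian stop runner.  The hybrid is
the synthetic-study default so that one dataset supports both model fits.

## Race likelihood

Let f_go/F_go be the go ex-Gaussian density/CDF and S_stop the stop-latency
survival.  Per trial:

* go response at rt: (1 − GF)·f_go(rt)
* go omission: GF + (1 − GF)·P(go RT > max_rt)
* signal-respond at rt: (1 − GF)·f_go(rt)·[TF + (1 − TF)·S_stop(rt − SSD)]
* successful stop: GF + (1 − GF)·[TF·S_go(max_rt) + (1 − TF)·(1 − I(SSD))],
  I(SSD) = ∫₀^max_rt f_go(t)·S_stop(t − SSD) dt.

A stop trial with no response is scored as a successful stop regardless of
its latent cause (go omission, deadline, stop runner winning): the causes are
observationally indistinguishable, so the GF term sits inside the
stop-success probability.  Stop latencies are truncated at zero — a response
at or before the stop signal cannot have lost the race — and the simulators
truncate identically, so analytic probabilities and Monte-Carlo frequencies
agree to sampling error.  Go-RT mass below 0 ms (≪ 1e−6 at realistic
parameters) is folded into the no-response term.

I(SSD) splits at the survival kink: the exact CDF difference below t = SSD
plus 128-node Gauss–Legendre on the smooth remainder [SSD, max_rt]
(integrating across the kink costs ~5 decimal digits).  Total probability
per (parameters, SSD) checks out to 1e−6 in the tests, and analytic
stop-success probabilities match 10⁶-trial simulated frequencies within 3
binomial SEs across an SSD × parameter grid.

## Diffusion model

First-passage densities use the standardized small-time and large-time
series, switching by the standard truncation-bound comparison with an error
budget of 1e−7 per evaluation.  Omission probabilities integrate both
defective densities with 256-node Gauss–Legendre (no closed-form survival is
needed at that accuracy).  Simulation is Euler–Maruyama at dt = 0.1 ms with
Brownian-bridge within-step crossing detection — without the bridge
correction, first-passage times are biased upward by O(√dt), which is visible
against the analytic density at 2·10⁵ trials.

Accuracy coding is the default (correct → upper boundary) with the start
point z free.  The original analysis describes z as a left/right bias yet
reports one value per cell; response coding is available behind a switch
(`coding="response"`), but accuracy coding with free z is the closest
single-model compromise and is what the recovery experiments exercise.  No
contaminant-uniform component and no inter-trial variability parameters
(sv, st₀, sz) are included — neither is reported for the study design this
mirrors.  With near-ceiling accuracy (ν = 4, a = 1.78 gives P(correct) ≈
0.999), a and z trade off along a ridge in single-subject maximum likelihood;
the hierarchical prior regularizes this, and the single-subject ML test
profiles z out for that reason.

## Hierarchical estimation

Transforms: log for σ, τ, a, t₀; probit for TF, GF, z; identity otherwise.
Subject values are Normal(group location, group scale) per transformed
parameter; hyperpriors are Normal on locations (broad, unit-aware: e.g.
μ_Stop location ~ N(200, 150) ms) and half-Normal on scales.  These are
weakly informative, recovery-validated substitutes — the original estimation
framework's exact priors are not reported.

Sampling is blocked DE-MCMC with 33 chains: per sweep,

1. each subject's parameters, updated in two blocks (go-side + GF, stop-side
   + TF for the race model; a/ν/t₀ and z/GF for the diffusion) with
   γ = 2.38/√(2·d_block) and a small uniform jitter;
2. each parameter's (location, log-scale) hyper pair as its own 2-d DE block
   (the prior factorizes), repeated three times per sweep;
3. a group-shift move per block: the same δ added to a block's group location
   and every subject's value.  The subject-level prior is invariant under
   this translation, so the Metropolis ratio involves only data likelihoods
   and the location hyperprior.  This decouples the slow location/subject
   random walk of the centered hierarchy; without it, location chains
   disagree for many hundreds of sweeps.

During burn-in only, a migration move (probability 0.05 per sweep) cyclically
permutes the states of a random subset of chains.  Defaults: 500 burn-in
sweeps, then 120 stored draws per chain with a thinning interval of 5 —
the stored-sample budget (33 × 120) mirrors the study's chain plan, and the
thinning keeps the stored window wide enough for honest R̂ at that budget.
Initialization jitters moment-based estimates (ex-Gaussian moments for the
race model, the closed-form EZ estimator for the diffusion); non-finite
starts are re-drawn up to a retry budget.

Diagnostics: classic Gelman–Rubin PSRF from between/within chain variances
(reported as undefined, never 1, when within-chain variance is zero) and an
effective sample size from chain-averaged autocovariances with Geyer
initial-positive-pair truncation.  At the default budget the recovery fits
reach ESS ≈ 250–450 on the stop-side group locations — the same order as the
~250 the original analysis reports — with R̂ typically below ~1.5;
`posterior_summary` refuses to summarize chains with R̂ ≥ 1.1 unless
explicitly overridden.

Group-level results are reported as the across-subject mean of subject-level
posterior means on the natural scale (ms / % / a.u.), which is directly
comparable to published group descriptive rows (mean ± between-subject SD).

## Synthetic study and recovery

The study generator emulates the published design: 38 participants × 2 tasks
× 3 conditions (100 trials Control, 50 Canal/Otolith), 70/30 go/stop,
staircase SSD, with per-cell generating means and between-subject SDs
defaulting to the published descriptive values for the stop-side race
parameters and the diffusion parameters.  The printed ± values conflate
estimation error with true between-subject spread; using them as
between-subject SDs is an acknowledged approximation.  Draws are independent
truncated normals per cell (no between-cell subject correlation by default).

Go-side ex-Gaussian generating values are not published.  When a race agent
is requested they derive from the printed go-RT summaries by a fixed
calibration: τ_go = 0.82·IIV, σ_go = √(IIV² − τ_go²), μ_go = RT_Tot − τ_go,
which reproduces the printed mean and SD exactly by the moment identities
(classical/Control: μ_go ≈ 360, σ_go ≈ 60, τ_go ≈ 86 ms).  The 0.82
exponential share is a conventional go-RT skew choice, fixed once.

What passing recovery shows — and does not.  The generator produces
stationary, independent trials with exactly the assumed likelihoods; real
data add sequential effects, fatigue, RT contaminants and model
misspecification.  Recovery therefore validates the estimation machinery
(likelihoods, sampler, diagnostics, reporting), not the models' adequacy for
any particular dataset.  Direction-of-effect checks (the Canal-vs-Control
σ_Stop contrast) use the ground-truth subject parameters rather than full
refits per replicate, which tests the effect-encoding and inference layer at
tractable cost, not end-to-end sensitivity.

Problem sizes: the recovery experiments use 12 subjects with 350 go + 150
stop trials (race) or 400 go trials (diffusion) per subject — enough for the
group posterior to sit well inside one between-subject SD while a full
recovery run stays in the minutes range on one CPU.

At 150 stop trials per subject the σ_Stop/τ_Stop split has substantial
sampling variability: an occasional replicate's dataset is genuinely best
explained by a small-σ/large-τ configuration (verified by comparing retained
likelihoods against the generating values under a truth-initialized
sampler).  The race recovery claim is therefore framed over independent
replicate experiments, with the per-parameter median over three replicates
as the robust summary (`race_recovery_median`); single replicates recover
≥ 4 of 5 stop-side parameters in most seeds but not all.  The diffusion
recovery is stable replicate-to-replicate and is reported from a single
experiment.

## Group statistics

Paired t-tests via the classical statistic on differences (identical samples
return the degenerate t = 0, p = 1; a nonzero constant difference is
rejected).  Holm step-down adjustment.  One-way repeated-measures ANOVA with
subject blocking (zero condition variation returns F = 0 by definition).
The JZS Bayes factor integrates the noncentral-t likelihood over a
Cauchy(0, 0.707) effect-size prior by adaptive quadrature split at the
likelihood peak; log(BF₁₀) uses the natural log — the published magnitudes
(e.g. 24.45, 36.01) are only consistent with natural-log JZS values at the
study's sample size.  The Bayesian repeated-measures ANOVA of the original
analysis chain (a g-prior mixture model) is not reproduced; a clearly
labelled BIC approximation is provided instead, and the original r-scale
settings are stored for documentation.  The evidence-label scale is the
standard Jeffreys-style one (the original's interpretation table is not
publicly available).

## Known limitations

* Stop-side group-location chains mix slowly at the 33 × 120 stored-sample
  budget; R̂ can sit between 1.1 and 1.5 even when recovery is accurate.
  Longer thinning or more stored draws resolve this at linear cost.
* The quantile-method SSRT uses nearest-rank selection (no interpolation),
  matching a "selected RT" reading; with < ~20 correct go RTs the estimate is
  coarse by construction.
* The race and diffusion models are fit separately (as in the design this
  mirrors); no joint go-process linkage is attempted.
* Sensorial-task angle effects on RT are a no-op hook: the generator places
  ±1–3° stimuli but does not modulate RT by eccentricity.
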