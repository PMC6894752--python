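# Methods

This note documents the models implemented in `socialfreeze`, the
assumptions behind them, the defaults that matter, and what the synthetic
data do and do not establish.

## Behavioral scoring

Freezing is scored by humans as bouts (start/stop seconds).  A bout counts
as freezing only if it lasts at least `min_bout_s = 3` s, the conventional
cutoff separating brief immobility from freezing; the cutoff is applied to
raw bouts *before* the union of overlapping bouts is taken, matching how
scorers apply the rule per logged bout.  Rasterization marks second `t`
frozen iff the half-open interval `[t, t+1)` is entirely covered by retained
bouts — a deterministic convention chosen because the scoring convention for
partially covered seconds is not standardised; it is conservative and makes
rasterize → extract-bouts → rasterize the identity on any series whose runs
respect the 3-s rule.  Epochs are half-open 710-s windows, baseline at 0 and
the shock epoch at the first shock (~720 s into a 24-minute test).

## Epoch-level coupling models

Each model explains one animal's epoch freezing proportion (two rows per
dyad) as a linear combination of products of covariates.  Partner terms are
always gated by the shock indicator (e.g. `Freezing_obs × Shock_dem`),
because shock-free epochs show no demonstrator–observer relation to model.
The likelihood is an **unbounded Normal on the proportion scale** — simple,
and adequate at typical freezing levels — so fitted values are not forced
into [0, 1]; only the data generator clamps.

Priors and bounds: coefficients get Normal(0, 2) priors restricted to
[−1, 1], relaxed to [−1.5, 1.5] for partner-coupling terms whose estimates
approach 1.  The residual SD prior is half-Normal(0, 2) — the residual-scale
prior is a package choice (weakly informative, positive); posterior results
are insensitive to it at n = 64 rows.

Sampling uses the affine-invariant ensemble sampler (emcee): 4 independent
ensembles of 10 walkers, 1000 warmup + 1000 kept steps thinned by 5 by
default.  Ensembles, not walkers, serve as chains for the rank-normalised
split-Rhat (walkers within an ensemble interact and are not independent
chains); any parameter with Rhat > 1.01 flags the fit as non-converged —
a warning and a `converged=False` flag, never a silent success.  Replicate
studies in the test suite use a lighter 400 + 500 schedule, which keeps
Rhat at or near the threshold while making 50-replicate studies affordable;
posterior means and 95% intervals are indistinguishable from the default
schedule at this model size.

Model scoring is PSIS-LOO via arviz on the pointwise log likelihood.
Points whose Pareto-k tail diagnostic exceeds 0.7 are re-scored by an exact
leave-one-out refit (capped at 10 points per model; beyond that the smoothed
estimate is kept with a warning).  Ranking follows the published decision
rule: order by elpd_loo; the top model wins outright if it leads every
runner-up by more than its own SE; otherwise runners-up within one SE are
compared pairwise against the top — a simpler nested model is preferred when
the top model's extra coefficients all have 90% intervals containing 0, and
a group-split (modulator) variant is kept only when the split parameters'
95% intervals do not overlap.  The two interval levels mirror the published
procedure (90% for parameter inclusion, 95% for the modulator-overlap rule)
and are both configurable, since the asymmetry appears intentional but is
not explained.

## Granger causality

Freezing series are smoothed with a normalized Gaussian kernel of SD 1.5
samples truncated to a 300-sample window ("size 300, sigma 1.5" is read as
window/SD in samples — the only reading in which both numbers are
meaningful), reflected at the edges.  Stationarity is screened per series
with the augmented Dickey–Fuller test (statsmodels); non-rejection warns
but never discards an epoch automatically.

The VAR order is selected by AIC, `n_eff·ln det Σ̂ + 2k`, on a common
effective sample.  F in each direction is the log ratio of reduced-to-full
residual variance for the target equation; both models are least-squares
fits on identical rows, so F ≥ 0 up to round-off.

Two numerical choices deserve emphasis:

* **Per-series demeaning (default).**  Freezing series are far from
  zero-mean.  Without centering or an intercept, the partner's lags act as
  extra estimators of the target's mean, and *independent* binary series
  with realistic freezing rates show F ≈ 0.05 — pure bias.  Each series is
  therefore demeaned (per dyad and per variable) before lag construction,
  which is also what the standard multivariate Granger toolbox does
  internally.  An explicit intercept is available as an option.
* **Calibrated significance.**  The asymptotic likelihood-ratio null
  `n_eff·F ~ χ²(m)` is anticonservative at epoch-length samples (measured
  6.7% type-I at the 5% level for n = 710, m = 21); the standard
  residual-degrees-of-freedom multiplier `(n_eff − k_full)·F ~ χ²(m)`
  brings it to 4.2% and is used throughout.

Pooling fits one model over all dyads by stacking per-dyad lagged blocks so
no lag window crosses a dyad boundary; the order is selected on the pooled
sample.  Demeaning per dyad also removes between-dyad level differences that
would otherwise masquerade as temporal coupling.  Dyads whose smoothed epoch
series are constant (not enough freezing variation) are flagged as
degenerate by the stationarity screen and should be excluded from per-dyad
estimates.

## Signal-detection simulator

The danger cue is a deterministic boxcar: 100 samples on, 100 off, five
cycles (1,000 samples).  Each agent adds iid Gaussian noise (SD σ; the
noisier animal of an unequal pair has `r·σ`, r ≥ 1) and freezes when its
internal signal exceeds threshold `c`.  Social agents add
`b·(f_partner[t−1] − 0.5)` — the partner's previous decision, weight `b`
for the noisier animal and `b/r` for the better-informed one.  The partner
state before t = 0 is taken as 0 (not freezing): the cue starts in the "on"
state, so this is the conservative initialisation; it is configurable.

ROC sweeps use 101 evenly spaced thresholds on [−5σ, +5σ] (the range is
prescribed, the count is a package choice); **each threshold is an
independent simulation with fresh noise**, matching re-run semantics, with
a common-noise option for variance reduction.  Points are sorted along the
curve, anchored at (0,0) and (1,1), and integrated by trapezoid.  For σ = 1
the closed-form equal-variance AUC is Φ(1/√2) ≈ 0.760, and the simulated
median over 20 repetitions sits within Monte-Carlo error of it.  Gains are
medians over 20 repetitions per (σ, b) cell; σ = 0 is excluded from sweeps
(degenerate threshold range).

## Synthetic data: what it emulates, and what it does not

The epoch-level generator draws the observer first — shock-epoch mean 0.55,
between-dyad SD 0.25, baseline mean 0 by default (an optional intercept can
mimic the sub-10% baseline freezing of shock-preexposed observers) — then
the demonstrator from the winning coupling model (0.47·Shock +
0.37·Freezing_obs·Shock, residual SD 0.12), clamping draws to [0, 1].
Clamping (rather than truncated re-sampling) keeps proportions valid while
mirroring the unbounded-Normal likelihood used in fitting.  When both
targets are given coupling terms (demonstrator→observer 0.85 *and*
observer→demonstrator 0.37), the bivariate linear system is solved per dyad
so both stated coefficients genuinely generate the data; fitted coefficients
under this simultaneous scheme carry simultaneity bias, so the end-to-end
claim tested is *detection* of both couplings (winners contain the terms,
intervals exclude 0), not unbiased recovery of their values.

There is no published per-second generative model for real freezing, so the
second-by-second generator reuses the simulator's threshold-agent recursion
with a shock-locked boxcar danger signal (60 s after each of five shocks at
720, 870, 1020, 1170, 1320 s; ISIs inside the study's 120–180 s range).
This stand-in has the right coarse structure — shock-locked drive, lag-1
mutual coupling, scoring-compatible bouts after short runs are removed —
but unrealistically high baseline freezing (~30% at σ = 1, c = 0.5) and no
bout-duration dynamics, ultrasonic vocalisations, or jumping beyond a
binary covariate.  Passing tests therefore demonstrate that the engines
detect the structure they model, at the study's sample sizes; they do not
validate the engines against idiosyncrasies of real scored freezing.

## Problem sizes used in the test suite

Replicate studies run at the study's scale where that is the claim being
tested: 32 dyads per cohort, 50 replicates for parameter/model recovery,
20 seeded end-to-end runs, 500 simulated pairs for null calibration
(n = 710, order 21), and 20-repetition medians for all simulator grids.
Analytic oracles (the ln 2 construction) use n = 20,000 with 5 replicates.

## Known limitations

* Noise is independent across simulated animals; correlated noise (shared
  environmental input) is out of scope, as is any evolutionary dynamics.
* The Bayesian engine fits exactly two rows per dyad; per-shock granularity
  is handled descriptively, not modelled.
* Granger results on near-saturated or near-silent epochs are fragile; the
  stationarity screen flags but does not repair them.
* WAIC ranking and analysis of the originally deposited recordings are not
  implemented (an event-log reader for the common export dialect is).
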