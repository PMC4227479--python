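# Methods

## The task environment

The dynamic reward task (DRT) is a two-alternative probabilistic choice
task. On each trial the subject picks one of two decks (A or B) and
receives a 1-point reward with the chosen deck's scheduled probability.
Within a block the per-deck probabilities are fixed; across the six
unsignalled testing blocks the advantageous deck alternates and the gain
ratio switches among 1:6, 6:1, 1:3 and 3:1, always summing to a total
gain probability of 0.6. Rewards are *non-baited*: each deck's reward
status is redrawn every trial, so nothing accumulates on the unchosen
deck and only the chosen deck needs a draw.

The two canonical testing sequences (six blocks of 70–90 trials, 480
trials total) and the 40-trial training block (ratio 1:6) are hard-coded;
their generative "pseudorandom" rule is not recoverable, so they are
treated as fixed study materials. The 1:6 split of 0.6 has no finite
decimal form; blocks store the exact values 3/35 and 18/35 (displayed as
8.57% / 51.43%) so the sum-to-0.6 invariant holds to floating-point
accuracy. Block boundaries are invisible to agents, and which physical
deck is advantageous in the training session is randomized per subject
(the mirrored variant carries the label `training-swapped` so serialized
data stay self-describing).

## The learning model

Choice behaviour is modelled with tabular Q-learning plus a softmax
choice rule:

* value update (chosen deck only): `Q(t+1) = Q(t) + α (R(t) − Q(t))`,
  with learning rate `α ∈ [0, 1]` and binary reward `R`;
* choice rule: `P_A = exp(βQ_A) / (exp(βQ_A) + exp(βQ_B))`, with choice
  perseveration (inverse temperature) `β ≥ 0`.

Both deck values start each session at zero, which forces `P = 0.5` on
the first trial; the choice on trial *t* is always driven by the
pre-choice Q-state. Only the chosen deck is updated — the non-baited
design provides no feedback about the unchosen deck — and no forgetting
or decay term is included. Likelihoods use natural logs with a floor of
1e-12 on per-trial choice probabilities so extreme `β` cannot produce
infinite log-likelihoods; base-2 logs appear only in the matching-law
analysis, where they are conventional. Training-session trials are
excluded from likelihood fitting (the training block is familiarization,
not measurement).

The vectorized kernels factor the likelihood through per-trial signed
Q-differences: the value recursion depends only on `α` and the data, so
one recursion per candidate `α` serves every `β` — this makes the MCMC
sampler and grid-search fitting cheap. Scalar reference implementations
are kept and cross-checked against the vectorized paths in the tests.

## Matching-law analysis

The generalized matching law `log2(C_A/C_B) = s·log2(R_A/R_B) + log2 k`
is fitted by OLS to block-level points: counts are taken over the
steady-state window (within-block trials 21–70, 1-based inclusive — 50
trials of a 70-trial block), blocks with zero rewards from either deck
are excluded (their log ratio is undefined), and points are pooled
across subjects within a group, yielding one sensitivity `s`, one bias
and one R² per group. Pooling follows from the reported group-level
degrees of freedom in the emulated study, which are of the order of the
number of block-points, not subjects. Slope differences between groups
use `t = (s₁ − s₂)/√(se₁² + se₂²)` on `n₁ + n₂ − 4` degrees of freedom
(two slopes and two intercepts estimated); the exact exclusion
bookkeeping behind the emulated study's printed dfs is unknown, so this
df rule is documented rather than asserted to match.

## Hierarchical Bayesian estimation

Subject parameters get hierarchical priors per group: probit-normal
learning rates (`alpha_i = Φ(z_i)`, `z_i ~ Normal(mu_g, sigma_g)`) and
log-normal perseveration, with weakly-informative hyperpriors
`mu_alpha ~ Normal(0, 1)`, `mu_logbeta ~ Normal(0, 1.5)` and
`sigma ~ Uniform(0, 5)`. These transforms and hyperpriors follow the
conventions of graphical-model cognitive Bayes; they are configuration,
not doctrine, and all are exposed on `HierModelSpec` so sensitivity
analyses are one argument away.

Sampling is adaptive Metropolis-within-Gibbs, written for this package:
random-walk proposals per subject (scales adapted during burn-in toward
~44% acceptance and frozen afterwards), conjugate Gibbs draws for group
means, log-scale random-walk updates for group scales, and independent
chains per group. The protocol contract is the burn-in/thinning
arithmetic: 3 chains × 28,000 iterations with 8,000 burned and thinning
5 retain exactly 12,000 draws. The desk-scale default
(3 × 4,000, burn 1,000, thin 5 → 1,800 draws) is used by the pipeline
and tests; on the 69-subject default cohort it runs in a few minutes on
one CPU with split-chain rank-normalized R-hat ≤ 1.01 on all group-level
parameters. Non-convergence (R-hat > 1.1) is flagged on the result and
warned about, never silenced.

Group comparisons report (i) the fraction of paired posterior draws in
which one group mean exceeds the other (ties count as not-greater), and
(ii) Savage–Dickey Bayes factors for the standardized group-mean
difference `δ = (mu₁ − mu₂)/σ_pool` on the latent (probit/log) scale
with a standard-normal prior at the null. The posterior density at zero
uses a normal approximation to the retained draws, cross-checked by a
Gaussian KDE; a >20% discrepancy raises a warning. Parameter–symptom
correlations use subject-level posterior means, Pearson correlation, and
a residual-on-residual partial correlation controlling for the z-scored
chlorpromazine-equivalent dose.

## Synthetic cohort generator

The generator emulates a three-group clinical design: controls (n=24),
low-psychosis (n=19) and high-psychosis (n=26) patients, each playing a
training session plus one of the two testing sequences (assigned by coin
flip). Group parameter distributions are calibrated so the implied
population means match the fitted group means of the emulated study —
learning rate 0.71/0.85/0.86 and perseveration 4.11/4.16/2.91 for
control/low/high — using the closed forms `E[Φ(Z)] = Φ(μ/√(1+σ²))` and
`E[exp(Z)] = exp(μ+σ²/2)`. The between-subject spreads (σ = 0.5 on both
latent scales) are free parameters chosen once for realistic individual
differences; the emulated study reports no subject-level spreads.

Patients receive two synthetic covariates. The PANSS p1+p3 score is a
linear function of the subject's true β (slope −0.05) plus Gaussian
noise (SD 0.8 low / 1.8 high), rounded and clipped to each group's
admissible range (2–4 and 4–14, which the group-splitting rule implies),
with group baselines 2.42 and 5.92. The link is a deliberately simple
stand-in calibrated by simulation so that the pooled partial correlation
between β and the score is ≈ −0.28 in expectation (target ≈ −0.26); most
of that pooled correlation comes from the group structure (high-psychosis
subjects have lower β and higher scores), not the weak within-group slope.
The chlorpromazine-equivalent dose is log-normal, moment-matched to the
published group means/SDs and independent of the model parameters.

Validation of the generator is behavioural, not circular: simulated
group mean total scores land within ±15 of the emulated study's
168.2/171.7/174.5, pooled matching sensitivities fall near the published
0.37/0.32/0.31 with the control group highest, and all groups
undermatch. What the generator does **not** emulate: response times,
side/position biases, attention lapses, within-session drift of
parameters, or any deviation from the Q-learning model itself — so
passing tests show the pipeline recovers what this model family
generates, not that real patients obey the model.

## Simulation grid

`run_grid` pairs α ∈ {0.05, …, 1.00} (step 0.05) with β ∈ {0.5, …, 10}
(step 0.5) — 400 pairs — and simulates 100 independent 480-trial
sessions per pair on sequence-1 (configurable; the two sequences give
indistinguishable landscapes). Each cell draws from an independent
substream spawned from the master seed and indexed by cell position, so
the grid is reproducible cell-by-cell and independent of evaluation
order. Mean total score peaks at an intermediate learning rate and
increases with β over the explored range; the ridge around the optimum
is flat (α 0.25–0.40 within ~0.3 points at high β against a per-cell
standard error of ~1.5 at 100 repetitions), so the location of the
single-run argmax wobbles by roughly one grid step around α ≈ 0.30–0.35.
Per-cell score SDs are sample SDs (ddof=1); with a single repetition the
SD is reported as 0 and a warning is raised. Ties in the argmax break
toward smaller α, then smaller β.

## Numerical and degenerate-input choices

* Softmax is computed as a logistic of the scaled value difference
  (`expit(β(Q_A − Q_B))`), which is stable for any finite inputs.
* Exact rational arithmetic (`fractions.Fraction`) underlies the
  probability splits; floats appear only at the boundary.
* `prob_diff_positive` uses strict inequality; with tied draws the
  greater/less/tie fractions sum to one.
* Savage–Dickey errors out on zero-variance posteriors rather than
  returning an infinite Bayes factor.
* Blocks shorter than the steady-state window raise by default
  (`allow_short=True` truncates instead); fewer than 3 usable
  block-points refuse to fit.

## Problem sizes used by the test suite

Unit and property tests run on reduced instances: tiny hand-built blocks
and 10-trial likelihood oracles, 12–15-subject cohorts for sampler
checks, and the desk-scale MCMC protocol for the full-cohort recovery
test. The simulation grid always runs at full size (400 cells × 100
sessions), which takes about a second per seed with the vectorized
engine. These sizes are the package's own defaults for routine
validation; the full 28,000-iteration protocol remains available through
`McmcSettings`.

## Known limitations

* The sampler is a random-walk scheme: effective sample sizes per
  retained draw are lower than gradient-based samplers would give; the
  retained-draw arithmetic, not sampler efficiency, is the contract.
* Group-level inferences at n ≈ 20–26 subjects inherit cohort sampling
  noise: the realized group mean of a drawn cohort can sit far from the
  generator's population mean, and the posterior tracks the realized
  cohort, as it should.
* No alternative learning rules (dual learning rates, forgetting,
  actor–critic) or choice rules (ε-greedy) are implemented; model
  comparison (WAIC/LOO) is out of scope.
* The PANSS covariate link is synthetic plumbing for pipeline testing;
  its numbers carry no clinical meaning.
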