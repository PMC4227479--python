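# dynreward

Modelling toolkit for the **dynamic reward task (DRT)** — a two-deck
probabilistic choice task whose deck reward probabilities swap across
unsignalled blocks (total gain probability fixed at 0.6, gain ratios
1:6 / 6:1 / 1:3 / 3:1, six blocks of 70–90 trials, 480 trials per
session). The DRT is used in computational psychiatry to probe reward
prediction error (RPE) processing: how quickly beliefs about reward are
updated (*belief formation*) and how strongly the currently-believed
better option is exploited (*belief perseveration*), for example when
comparing patients with schizophrenia to healthy controls.

The package is aimed at cognitive-modelling and computational-psychiatry
researchers who want a tested, reproducible implementation of the whole
analysis chain:

* **Task simulation** — exact block schedules, non-baited reward
  generation, fully seeded.
* **Q-learning model** — value update
  `Q(t+1) = Q(t) + α(R(t) − Q(t))` for the chosen deck and softmax
  choice rule `P_A = e^{βQ_A}/(e^{βQ_A} + e^{βQ_B})`; trial-by-trial
  likelihoods, ML grid fitting, forward simulation.
* **Generalized matching law** —
  `log₂(C_A/C_B) = s·log₂(R_A/R_B) + log₂k` fitted by OLS over
  steady-state block counts (trials 21–70), with group slope
  comparisons; `s < 1` is undermatching.
* **Hierarchical Bayesian estimation** — probit-normal learning rates,
  log-normal perseveration, adaptive Metropolis-within-Gibbs MCMC,
  posterior group-difference probabilities and Savage–Dickey Bayes
  factors, parameter–symptom correlations.
* **Synthetic cohorts** — a generator emulating a three-group clinical
  study design (24 controls, 19 low-psychosis, 26 high-psychosis) with
  ground-truth parameters retained for recovery testing.
* **Performance grid** — the 20×20 (α, β) simulation mapping total
  score over the parameter space.

See `docs/methods.md` for the full model description, calibration
choices and limitations.

## Worked example

```python
import numpy as np
from dynreward import (sample_cohort, default_study_specs,
                       filter_blocks, fit_matching)
from dynreward.matching import aggregate_subject
from dynreward.grid import run_grid, locate_optimum

cohort = sample_cohort(default_study_specs(), np.random.default_rng(1))
for group, subs in cohort.by_group().items():
    scores = [s.total_score for s in subs]
    aggs = [a for s in subs for a in aggregate_subject(s)]
    fit = fit_matching(filter_blocks(aggs))
    print(f"{group:15s} n={len(subs):2d} score={np.mean(scores):6.1f} "
          f"s={fit.sensitivity:.3f} (se {fit.se_sensitivity:.3f}, R2 {fit.r_squared:.2f})")

grid = run_grid(n_reps=100, seed=1)
alpha, beta, score = locate_optimum(grid)
print(f"grid optimum: alpha={alpha:.2f} beta={beta:.1f} mean score={score:.1f}")
print(f"cell-score SD range: {grid.sd_score.min():.2f} - {grid.sd_score.max():.2f}")
```

prints

```
control         n=24 score= 171.4 s=0.325 (se 0.014, R2 0.82)
low-psychosis   n=19 score= 168.8 s=0.311 (se 0.017, R2 0.81)
high-psychosis  n=26 score= 164.6 s=0.257 (se 0.012, R2 0.79)
grid optimum: alpha=0.35 beta=10.0 mean score=203.9
cell-score SD range: 8.65 - 16.05
```

Reading the output: the three synthetic groups score similarly overall
(~165–175 of 480 points) while their matching-law reward sensitivities
separate, with controls highest — total score is a blunt measure, reward
sensitivity is not. All groups undermatch (`s < 1`). The performance
grid shows that score is maximized at an *intermediate* learning rate
(α ≈ 0.3–0.35) combined with strong perseveration — updating beliefs
faster is not better in a blockwise-switching environment — and the
per-cell score SDs span roughly 9–16 points.

The hierarchical fit is the slower stage (minutes, not seconds):

```python
from dynreward import fit_hierarchical
from dynreward.hb import reduced_settings

result = fit_hierarchical(cohort.by_group(), settings=reduced_settings(1))
print(result.summaries())   # posterior means and 95% CIs per group
print(result.rhat)          # split-chain convergence diagnostics
```

## Command line

The `drt` console script exposes the same steps:

```bash
drt schedule show --label sequence-1
drt simulate agent --alpha 0.35 --beta 7 --schedule sequence-1 --seed 1 --out agent.csv
drt synth cohort --seed 1 --outdir cohort/
drt match fit --trials cohort/trials.csv --group control --out fit.json
drt fit hb --trials cohort/trials.csv --seed 1 --out posterior/
drt simgrid run --reps 100 --seed 1 --out grid.csv
drt run --seed 1 --outdir report/        # full pipeline on a synthetic cohort
```

All file formats are plain CSV/JSON; schemas are documented in
`src/dynreward/io.py`.

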