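# costdiscount

Cost-benefit choice modelling for physical effort and temporal delay:

- **Value models** — hyperbolic, linear, quadratic, two-parameter power, and
  an inverse-sigmoidal model (initially concave, turning point `p`, converges
  to zero) with a softmax choice rule and an optional utility transform
  (`M -> M^alpha`, default `alpha = 0.8` for the utility variant).
- **Bayesian fitting** (`costdiscount.vb`) — per-subject MAP + Laplace
  estimation over a grid of initializations, returning a free-energy model
  evidence that decomposes exactly as `F = accuracy - complexity`
  (second-order expected log-likelihood minus the Gaussian KL divergence from
  posterior to prior), plus a brute-force grid-integration oracle for
  validating the approximation and a prior-covariance sensitivity check.
- **Group model comparison** (`costdiscount.bms`) — random-effects Bayesian
  model selection over a subjects-by-models evidence table: variational
  Dirichlet updates, posterior model frequencies (`mp`) and exceedance
  probabilities (`xp`; exact Beta formula for two models, seeded Monte Carlo
  otherwise).
- **Staircase analysis** (`costdiscount.staircase`) — a PEST engine
  (halve-on-reversal, doubling on sustained runs, re-initialization at a
  quarter of the initial step) driving six interleaved staircases per block,
  psychometric logistic fits of indifference points, raw / multiplicative /
  additive representations, and the chord-based concavity classifier.
- **Synthetic cohorts** (`costdiscount.cohort`) — a discriminative
  two-block stimulus designer (pairs retained only where simulated
  hyperbolic / linear / concave deciders disagree; trivial and high-cost
  pairs rationed) and softmax agents with known ground-truth parameters.
- **Reporting** (`costdiscount.io`, `costdiscount.regress`,
  `costdiscount.pipeline`) — CSV trial/fit tables, per-subject choice
  logistic regression, fatigue permutation screens, cross-task parameter
  correlations, and a fully seeded end-to-end pipeline with a checksum
  manifest.

Everything is deterministic given the configured seeds.

## CLI

```sh
costdiscount demo --outdir demo_out --seed 1        # full synthetic study
costdiscount simulate --outdir out --seed 1         # stimuli + cohort -> trials CSV
costdiscount fit --trials out/trials_effort.csv --out out/fits.csv
costdiscount compare --fits out/fits.csv --out out/bms.csv
costdiscount staircase --model sigmoidal --k 10 --p 0.7 --beta 0.5 --out out/ip.csv
costdiscount report --trials out/trials_effort.csv --out out/report.json
```

All commands accept a YAML config (`--config`); unknown keys are rejected.
The pipeline writes trial tables, fit tables (subject, model, native
parameters, free energy, accuracy, complexity, predicted-choice accuracy),
BMS reports, indifference-point tables, and a `manifest.json` recording
versions, seeds, the defaults in effect, and SHA-256 checksums of every
output.

## Notes on defaults

- Estimation space: `ln k`, `ln beta` (priors `N(0, 10)`), turning point `p`
  identity (`N(0.5, 1)`); the power exponent is log-transformed. These
  priors are package defaults (stress-test with
  `costdiscount.prior_sensitivity`), and the turning point is deliberately
  not clipped at 1.
- Staircase effort levels default to `[0.15, 0.25, 0.4, 0.55, 0.75, 1.0]`
  (two slightly different level sets circulate for this design; the levels
  are configurable via `StaircaseConfig`).
- `fit_model` defaults to 8 initializations per free parameter (full
  factorial); pass `n_init_per_param=2..4` for large simulation studies.
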