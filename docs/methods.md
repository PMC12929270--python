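# Methods

## The measurement problem

A participant slides a fingertip left-to-right over a flat display and, after a
transient auditory (A), tactile (T), or synchronized auditory-tactile (AT)
stimulus, reports whether the finger was left or right of a visually displayed
midline at stimulus onset (two-alternative forced choice).  Stimulus position
`x` is expressed in signed cm, 0 at the midline, negative = left.  The
probability of a "right" report is modelled as a lapse-corrected cumulative
Gaussian (probit):

    psi(x) = lambda + (1 - 2 lambda) / 2 * erfc( -beta (x - alpha) / sqrt(2) )
           = lambda + (1 - 2 lambda) * Phi( beta (x - alpha) )

* **alpha** (threshold, cm): the position where p = 0.5.  Its deviation from 0
  measures localization *bias* (negative alpha = rightward report bias).
* **beta** (slope, per cm): localization *precision*; the model works with
  log10(beta) so the slope is positive by construction.
* **lambda** (lapse rate): stimulus-independent errors compressing the curve
  into [lambda, 1 - lambda]; a single lapse governs both asymptotes and is
  condition-independent (conditions were not expected to affect lapses).

## Hierarchical model

The AT condition is the intercept of the linear predictors; T and A enter
through per-subject additive difference coefficients (dummy variables isT,
isA, never both 1):

    alpha_i  = coef_alphaAT_k + coef_alphaAT-T_k * isT_i + coef_alphaAT-A_k * isA_i
    beta_i   = 10 ^ (coef_betaAT_k + coef_betaAT-T_k * isT_i + coef_betaAT-A_k * isA_i)
    lambda_i = logistic(coef_lambda_k)
    y_i ~ Binomial(n_i, psi_i)

Note the difference coefficients, despite the "AT−T"/"AT−A" naming convention,
equal alpha_T − alpha_AT and alpha_A − alpha_AT (they are what is *added* to
the AT intercept in the T/A conditions).

Observations are binomial batches aggregated per (subject, condition,
position); the parameter-free normalizing constant log C(n, y) is kept so that
the likelihood is the exact binomial PMF.  Each of the seven coefficient
families (3 threshold, 3 log10-slope, 1 logit-lapse) has subject-level values
drawn from Normal(mu_f, sigma_f).  Hyperpriors (identical for both
experiments; only the stimulus range differs, ±2 cm blocked vs ±3 cm
interleaved):

| family              | mu prior       | sigma prior      |
|---------------------|----------------|------------------|
| threshold intercept | Normal(0, 1)   | half-Normal(1)   |
| threshold diffs     | Normal(0, 0.5) | half-Normal(0.5) |
| log10-slope intercept | Normal(1, 0.5) | half-Normal(0.5) |
| log10-slope diffs   | Normal(0, 0.25)| half-Normal(0.25)|
| logit-lapse         | Normal(−4, 1)  | half-Normal(1)   |

The SD priors are the positivity-constrained (half-normal) reading of the
printed normal scales; the logit-lapse group-SD scale is not printed anywhere,
so half-Normal(0, 1) mirrors its group-mean scale (configurable in the
hyperprior table).  The fitted model's alpha is unbounded under its normal
hyperprior; the ±range constraint applies to the adaptive procedure's grid,
not to the regression.

## Sampling

No probabilistic-programming backend is assumed: the sampler is a No-U-Turn
sampler (dynamic HMC, slice variant, multiplicative doubling, max tree depth
10) written against the model's analytic gradient, with dual-averaging step
size and windowed diagonal-metric adaptation.  The target is the non-centered
parameterization (coef = mu + sigma * z, z ~ N(0,1); sigma sampled on the log
scale with the Jacobian term), which removes the funnel geometry that centered
hierarchical scales exhibit with ~20 subjects.  The gradient is validated
against central finite differences, and the sampler against dense-grid
quadrature on 1-D and 2-D reductions, in the test suite.

Reference run configuration: 4 chains × 5,000 iterations, the first 2,500 of
each discarded as warmup — 10,000 retained draws.  The default acceptance
target is 0.95 (finer steps than the common 0.8): with short two-chain runs,
the group-SD parameters are the slowest-mixing coordinates and the smaller
step size is the standard remedy; the cost is ~30% more gradient evaluations.

A fit "passes" only through the diagnostics gate, evaluated per scalar
parameter: zero divergent transitions, no tree-depth saturation, E-BFMI > 0.2
per chain, rank-normalized bulk-ESS > 10% of total draws, mean-MCSE
(SD/sqrt(ESS)) < 10% of the posterior SD, and rank-normalized split-Rhat
≤ 1.01 (computed with arviz).  "Bulk-ESS" and "mean-MCSE" are the
contemporary default flavors; the gate records failures rather than raising.

## Inference outputs

* **Condition summaries**: posterior medians and 95% highest-density intervals
  of the condition-level population means — AT: (mu_alphaAT, mu_betaAT);
  T: (mu_alphaAT + mu_alphaAT-T, mu_betaAT + mu_betaAT-T); A analogously.
* **Contrasts**: draw-counting posterior probabilities from 10^5 seeded
  resamples of the pooled draws.  Thresholds: bilateral,
  P = 2·min(fraction > 0, fraction < 0) capped at 1 (the standard
  draw-counting analogue of a two-sided test; the formula itself is a package
  choice).  Slopes, unimodal vs bimodal: unilateral with the preregistered
  direction "bimodal steeper" — the contrast is oriented bimodal − unimodal
  and P = fraction ≤ 0 is the posterior probability of the null direction
  (unimodal slope at least as steep).  Slope A vs T: bilateral.  The null is
  rejected at P < 0.05.
* **Expected curves**: 10^4 seeded posterior draws of the condition-level
  population function; pointwise 2.5th/50th/97.5th percentiles over the
  stimulus grid.  The curve's lapse uses the logistic of the group-mean
  logit-lapse (the population-mean convention; a per-draw subject-integrated
  lapse would widen the envelope slightly and is a possible alternative).
  Interpretation: the expected function for a new, unobserved participant.

## Psi-type adaptive placement

The synthetic sessions place stimuli with a grid-based Bayesian adaptive
procedure: a joint posterior mass over (alpha, beta, lambda) starts from
uniform alpha and beta priors and a half-normal(0, 0.5) lambda prior
renormalized on its grid, is updated by Bayes' rule after every response, and
each trial presents the candidate minimizing the expected posterior Shannon
entropy over the two possible responses.  Grids: alpha and the candidate set
share the experiment's range (±2 or ±3 cm) in 0.5-mm steps (81/121 points);
beta spans [0.05, 5] per cm with 31 log-spaced points (log spacing matches the
slope's multiplicative role); lambda spans [0, 0.2] with 21 linear points.
The 81–121 × 31 × 21 joint stays tractable per trial because the expected
entropy rearranges into three cached likelihood-table matrix-vector products
per candidate set (no per-candidate posterior materialization), and the
single lapse parameter estimates both asymptotes jointly.

**Selection objective.** By default the lapse is marginalized out of the
entropy objective during placement (psi-marginal style): selection minimizes
the expected entropy of the (alpha, beta) marginal, while the lapse stays in
the tracked joint and is updated by every response.  Full-joint entropy
minimization is available behind the same operation, but measured on these
grids it spends roughly a third of the trials at the range extremes probing
the nearly-flat lapse prior and ends with a *larger* posterior threshold
variance than uniformly random placement (0.027 vs 0.023 cm² after 100
trials), whereas the marginalized objective beats random on both variance
(0.020 cm²) and absolute threshold error.  Since the procedure's purpose here
is efficient threshold/slope estimation, the marginalized objective is the
default.  On a single-lapse grid the two objectives coincide (tested).

## Synthetic experiments

`simulate_experiment` emulates the reference experimental structure: K = 20 subjects by
default, each coefficient drawn from its family's population normal; 300
trials per subject (100 per condition); independent psi states per condition
advanced in schedule order.  Schedules: the blocked design is 12 blocks of 25
single-modality trials with each modality exactly once per 3-block
randomization window; the interleaved design is 10 blocks of 30 with each
aligned 6-trial window a permutation of each modality twice.  A pre-session
one-up one-down staircase analogue (ends at 10 reversals, returns the mean of
the last 9 reversal levels) models the auditory-to-tactile intensity matching;
its step size and start level are hardware-specific in the real procedure and
are exposed as parameters — it feeds nothing downstream because stimulus
intensity is outside the localization model.  Missed presentations (optional
per-modality miss probability, default 0) are logged with a `repeated` flag,
do not update the psi state, and trigger one re-presentation of the same
stimulus.

Default generating population (chosen once to mirror the interleaved
experiment's qualitative findings — all thresholds negative with AT least
negative, log10-slopes ordered A < T ≲ AT, lapse near logistic(−4)):

    mu    = (−0.40, −0.35, −0.45, 0.30, −0.05, −0.35, −4.0)
    sigma = ( 0.50,  0.30,  0.30, 0.15,  0.10,  0.10,  0.5)

in the family order (threshold AT / T-diff / A-diff, log10-slope AT / T-diff /
A-diff, logit-lapse).

**What the generator does not emulate:** scanning-velocity variation, finger
kinematics and stimulus physics (localization data is fully characterized by
condition, position and response); psychoacoustic loudness; any mechanistic
model of the rightward bias (it enters only through negative generating
thresholds); real subjects' departures from the probit form or from normal
population distributions.  Passing recovery tests therefore demonstrate that
the estimation machinery is correct and calibrated under the model's own
assumptions, not that the model is adequate for any particular real dataset.

## Problem sizes and numerics

The packaged verification runs are scaled for a single CPU: recovery uses 10
subjects × 150 trials with 2 chains × (1,500 warmup + 1,000 kept) draws per
seed over a 3-seed battery; the adaptive-procedure check uses 200 trials × 20
replicate seeds; the reference 4 × 5,000 configuration remains the default for
real fits.  Numerical details: response probabilities are clipped to
[1e−300, 1 − 1e−16] inside the likelihood only to avoid log(0) at unreachable
parameter values; a non-finite log posterior is reported to the sampler as −∞
with zero gradient (a rejected step, never a NaN accept statistic); psi mass
renormalization uses a two-pass sum so the state invariant (mass sums to 1
within 1e−12) holds exactly; expected-entropy ties within 1e−12 are broken by
a seeded uniform choice among minimizers; chain seeds are spawned from a
single root seed, so every artifact is bit-reproducible given (data, seed).

## Known limitations

* Posterior draws persisted to CSV drop sampler telemetry, so the diagnostics
  gate cannot be re-evaluated from a reloaded file (summaries, contrasts and
  curves can).
* E-BFMI, divergences and tree depth are populated by the built-in NUTS
  backend; an alternative backend that does not expose them would have those
  clauses excluded from the gate (fields marked not-applicable).
* The blocked-design psi runs advance strictly in block order by
  construction; no within-block interleaving variant is modelled.
* With strongly non-probit observers or heavy-tailed populations, the
  hierarchical normal assumptions are misspecified; nothing in the synthetic
  recovery loop would reveal that.
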