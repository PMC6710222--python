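# Methods

## The model

`lbaselect` studies how nine model-selection methods behave when deciding
which parameters of a Linear Ballistic Accumulator (LBA) differ between two
within-subject conditions. The LBA treats a two-choice decision as a race
between one accumulator per response. On each trial, accumulator *i* starts
at a point drawn uniformly from [0, A], accrues evidence linearly at a
drift rate drawn from a normal distribution with mean *v_i* and SD *sv_i*
truncated below at zero, and triggers its response on reaching the
threshold *b*; the observed response time adds a non-decision time *t0*.
Because drifts are truncated to positive values, every accumulator finishes
almost surely, and the two defective densities — the winner's first-passage
density times the loser's survivor function — integrate exactly to the two
response probabilities. The closed-form single-accumulator density and CDF
are the standard LBA expressions, renormalized by Φ(v/sv) for the
truncation; the A → 0 limit (deterministic start point) is handled
analytically.

Per convention, *t0*, *A* and *b* are shared across accumulators, the
correct and error accumulators get their own drift means (*v_c*, *v_e*) and
SDs, and *sv_c* = 1 fixes the scale.

## The model space

Four nested variants encode the possible condition effects: **null**
(nothing varies; 6 free parameters), **drift** (*v_c* varies; 7),
**threshold** (*b* varies; 7), **complex** (both vary; 8). The threshold is
sampled as B = b − A so the prior support is rectangular; b = A + B.
Default priors (TN(mean, SD, 0, ∞)):

| parameter | prior |
|---|---|
| v_c | TN(3, 3, 0, ∞) |
| v_e | TN(2, 3, 0, ∞) |
| sv_e | TN(2, 3, 0, ∞) |
| A | TN(2, 2, 0, ∞) |
| b − A | TN(2, 2, 0, ∞) |
| t0 | TN(0.5, 0.5, 0, ∞) |

In the per-condition parameterization each condition's varying parameter
receives an independent copy of its prior. The mean/difference
parameterization replaces the two copies with X_mean (same default prior)
and X_diff (X_1 = X_mean − X_diff, X_2 = X_mean + X_diff), where X_diff
carries a zero-mean normal prior whose SD sets the informativeness level:
UP (10), WIP (1), MIP (0.1), HIP (0.01). X_diff is left untruncated; draws
whose mapped condition parameters leave the support (e.g. a negative
drift mean) receive a −∞ log-prior. This makes the joint prior of the
mean-diff models a truncated product whose normalizing constant is
absorbed into the marginal likelihood — the same convention for all
variants, so Bayes-factor comparisons remain coherent.

## Posterior sampling

Posteriors are estimated by differential-evolution MCMC: 3k chains for k
free parameters, 1000 burn-in and 1000 retained iterations per chain by
default. Proposals are θ\* = θ_i + γ(θ_m − θ_n) + ε with γ = 2.38/√(2k),
ε uniform on ±0.001 per coordinate, and m ≠ n ≠ i drawn from the
population. During burn-in a migration step (probability 0.05 per
iteration) cycles states through a random chain subset to reabsorb outlier
chains. Chains initialize from prior draws re-drawn until the log-posterior
is finite (at most 1000 attempts). The per-trial likelihood is floored at
1e-10 before logs so single outlier trials cannot produce −∞ during
sampling; the floor is exposed in the model constructor.

A split-chain R̂ is reported per parameter. Values above 1.1 flag slow
mixing; the LBA posterior has a well-known soft ridge trading off A, b − A
and t0 on which mixing is slowest, and on finite datasets the posterior can
sit away from the generating values along that ridge.

## The nine selection methods

With L̂ the best per-draw log-likelihood in the posterior sample (the
study's maximum-likelihood convention), S draws, n trials:

* **AIC** = −2(L̂ − k); **BIC** = −2(L̂ − ½ k log n), n = total trials
  across both conditions (600 at default).
* **DIC** uses D̄ = mean per-draw log-likelihood and the minimum-deviance
  point estimate: P_D = max(log-lik) − D̄, DIC = −2(D̄ − P_D). **DIC_p**
  applies the same mechanics to the unnormalized log-posterior.
* **WAIC**: lpd = Σ_i log mean_s p(y_i|θ_s), penalty = Σ_i var_s of the
  per-trial log-likelihood (sample variance, denominator S − 1).
* **BF-BS**: bridge sampling with the optimal bridge. The posterior sample
  is split in half — the first half moment-matches a multivariate-normal
  proposal, the second half enters the iteration; as many proposal draws
  are taken as there are posterior draws; iteration stops at a relative
  tolerance of 1e-10 or 1000 iterations (non-convergence is flagged).
* **BF-TI**: thermodynamic integration over power posteriors
  p(y|θ)^t · p(θ) on a 40-rung fifth-power ladder t_j = ((j−1)/(J−1))^5,
  integrating the per-temperature mean log-likelihood by the trapezoid
  rule. All temperatures run as one DE-MCMC population with one chain per
  rung. Two choices here were forced by accuracy diagnostics rather than
  taken from common defaults: (1) proposal difference vectors are drawn
  from chains within ±3 ladder positions (with a 10% chance of a global
  pair), because population-wide differences are mis-scaled for any single
  power posterior and stall the chains; (2) parallel-tempering swaps
  between adjacent rungs run every iteration, which lets heat flow along
  the ladder and removes multi-nat errors we observed with isolated
  chains. Both were validated against analytic conjugate marginal
  likelihoods and a large-sample prior-importance-sampling reference on a
  small LBA fit. The integrand spans roughly −9000 (prior, floored trials)
  to the posterior mean log-likelihood, so coarse ladders (J ≲ 20) carry
  several nats of discretization error at 600 trials: reduce `keep` to
  save time, not the rung count.
* **ROPE_a** (augmented region of practical equivalence): from the complex
  model's posterior, each condition difference (v_c,2 − v_c,1 and
  b_2 − b_1) is declared "present" iff more than half its draws fall
  outside its ROPE (v_c: ±0.3, b: ±0.11 — the design's small effect
  sizes); exact ties count as absent. The two binary decisions combine
  into one of the four variants.
* **χ²** relative-deviance tree at α = 0.05 (configurable): the better
  single-effect model is tested against the null (df 1); if significant,
  against the complex model (df 1); otherwise null vs complex
  (df 2, the parameter-count difference).

## Scoring

Deviance-scale values become model probabilities via exp(−0.5·Δ) weights,
marginal likelihoods via exp(Δ) weights (best value subtracted first).
ROPE_a weights multiply per-effect posterior proportions (outside the ROPE
for variants containing the effect, inside otherwise) and renormalize —
the two effects are treated as independent binary cases; this product
construction is our reconstruction of an under-specified convention, so
figures based on ROPE weights should be read accordingly. Brier scores use
the R-outcome quadratic rule, rescaled so that a perfect forecast scores 1,
the uniform forecast 0, and all mass on a wrong model −1; the map is
piecewise linear on each side of the chance point. Only the three anchors
are fixed by the convention we follow; the piecewise-linear interpolation
between them is a reconstruction, so Brier values are comparable within
this package but not figure-exact against other implementations. The χ²
test yields no probabilities and is excluded from Brier scoring.

## The synthetic design

Every dataset is one simulated participant: two conditions, 300 trials per
condition by default. Baseline parameters v_c = 3, v_e = 2, sv_c = sv_e = 1,
A = 1, b = 2, t0 = 0.3. Drift effects raise v_c in condition 2 to
3.3/3.75/4.25 (small/moderate/large); threshold effects lower b to
1.89/1.74/1.595. Two-way cells combine the two factorially, either
"extreme" (both effects speed up condition 2) or "balanced" (the threshold
drop lands in condition 1, largely offsetting the drift effect in the RT
distributions). That yields 6 one-way, 18 two-way and 1 null cell — 25
cells, 100 replicates each (2500 datasets, 10,000 fits, 90,000 metric
evaluations in the full study). Replicates share generating parameters;
seeds derive deterministically from (master seed, cell, replicate), so any
cell is reproducible in isolation.

The parameter changes were calibrated so that small/moderate/large
correspond to standardized RT differences of about 0.2/0.5/0.8 between
conditions. `calibrate_effect_size` recomputes this as the pooled-SD
standardized mean difference over all trials (correct and error pooled),
baseline minus manipulated — both manipulations speed responses up, so the
statistic is positive. Trials slower than 5 s are excluded, the trimming
routinely applied to empirical RT data; the trim is also what makes the
statistic well defined, because with zero-truncated drifts the LBA's RT
tail is a power law with infinite variance, and the untrimmed sample SD is
dominated by rare extreme trials. The exact statistic behind the original
calibration is not fixed by the convention we follow (which RTs, which SD,
which trimming); under this definition the six manipulations reproduce
≈ 0.20/0.50/0.81 (drift) and ≈ 0.20/0.49/0.79 (threshold) at 2×10⁵ trials
per condition, stable to ±0.01 across seeds.

What the generator does *not* emulate: real participants' parameter
heterogeneity, contaminant responses, sequential effects, and fatigue.
Passing tests therefore demonstrate method behavior under a correctly
specified LBA, not robustness to model misspecification.

## Problem sizes used in the test suite

The full 2500-dataset grid is a cluster-scale computation. The package's
own validation uses reduced problem sizes, chosen as the smallest runs
whose conclusions were stable across seeds in our checks:

* qualitative replication: 20 replicates each of the moderate/moderate
  "extreme" cell and the null cell at 300 trials/condition, fits with 3k
  chains and 400/400 burn/keep, TI at 40 temperatures with 600 burn-in and
  1500 retained iterations;
* parameter recovery: 10 replicates of the complex model at 1000
  trials/condition, 1000/500 burn/keep;
* marginal-likelihood validation: normal–normal and beta–binomial
  conjugate models at 10⁴ draws, plus a 50-trial LBA fit.

At these sizes the Bayes-factor estimates carry Monte-Carlo noise of a few
tenths of a nat; decisions with margins under ~1 nat (which occur for
genuinely borderline replicates) can flip between runs. That is a property
of the estimators at this scale, and the replicate-level acceptance
thresholds (e.g. ≥ 90% correct) absorb it.

## Known limitations

* Single-participant models only; no hierarchical structure.
* The ROPE weight construction and the Brier rescaling are documented
  reconstructions (see above).
* TI and bridge estimates agree to ~0.1–0.2 nats at the validation sizes;
  residual disagreement shrinks with longer runs but is not driven to zero.
* The χ² tree assumes the asymptotic χ² distribution of deviance
  differences, with the null-vs-complex comparison at df = 2.
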