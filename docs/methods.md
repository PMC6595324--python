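# Methods

`survinteract` implements seven procedures for testing whether a continuous
biomarker Z modifies the treatment effect (the hazard ratio between two
randomized arms) in a time-to-event trial, together with the simulation
machinery to study their type-I error and power.

## Data-generating model

A trial of n subjects is simulated as: Z ~ Uniform(0, 1); arm T ~
Bernoulli(1/2); event time E ~ Exponential(rate = λ(Z, T)); censoring time
C ~ Exponential(λ_cens), independent of everything; observed time
min(E, C) with event indicator 1{E ≤ C}. All hazards are constant in time,
so the treated:control hazard ratio HR(z) = λ(z, 1)/λ(z, 0) fully describes
the interaction.

Six scenarios define λ(z, T):

| # | control λ(z,0) | treated λ(z,1) | HR(z) | interaction |
|---|---|---|---|---|
| 1 | 1 | 1 | 1 | none |
| 2 | 0.5·e^{(2z−1)²} | e^{(2z−1)²} | 2 | none (prognostic only) |
| 3 | 0.7·e^{0.5z} | 0.7·e^{1.25z} | e^{0.75z} | log-linear |
| 4 | 0.9 | 0.35·e^{1.7√z − 0.2z² − 0.3z} | 0.389·e^{…} | qualitative, monotone |
| 5 | 0.9 | 0.9 + 1.75·z⁸ | (0.9 + 1.75z⁸)/0.9 | late-onset |
| 6 | 0.75·e^{0.4(2z−1)²} | 1.25·e^{−0.5(2z−1)²} | (5/3)·e^{−0.9(2z−1)²} | non-monotone |

The Scenario 4 treated-arm exponent uses √z. With this form the hazard
ratio crosses 1 at z = 0.424 (1.7√0.424 − 0.2·0.424² − 0.3·0.424 = 0.944 =
−ln 0.389), the defining feature of the scenario; a plain-z exponent would
put the crossing near 0.56 instead.

Censoring rates 0.3 and 2 give about 23% and 67% censored observations when
the event hazard is 1 (competing exponentials: P(event) = λ/(λ + λ_cens)).
Default sample sizes are 250, 500, 1000. Z values are drawn on the open
interval: an exact 0 (a measure-zero float event) is nudged to the smallest
positive double so logarithmic and negative-power transforms stay defined.

What the generator deliberately omits: non-uniform biomarker distributions,
covariate-dependent censoring, additional prognostic covariates,
non-proportional hazards within arm, and measurement error in Z. Rates
reproduced under this generator therefore say nothing about robustness to
those features of real trials.

## Cox engine

All methods are built on one weighted Cox partial-likelihood engine
(Breslow convention for ties, Newton–Raphson with step-halving, tolerance
1e-8 on the relative log-likelihood change plus one polishing step, max 50
iterations). The polishing step matters: it drives the score norm to ~1e-14
so that fits agree with tightly converged reference implementations to
1e-6. Separation (monotone likelihood) is detected when the fitted linear
predictor spans more than 35 on the log scale — a relative-risk spread of
e^35 — and is reported as non-convergence; callers then return p = 1, a
deliberately conservative convention also used for any other failed fit,
and the study harness counts and reports such failures per cell. Ties in
imported CSV data use the same Breslow convention; simulated times are
continuous and tie-free with probability one. Covariates are used
unstandardized so the reported coefficients are those of the model as
written.

## The seven tests

* **Median split** — I(z ≥ median), T, product; Wald test of the product
  term (1 df). Ties at the cutpoint go to the upper group.
* **Quartile split** — type-7 empirical quartiles, dummy coding with the
  lowest quarter as reference; 3-df LRT of the three interaction terms.
* **Optimal split** — every cutpoint leaving at least 10% of the sample on
  each side is tried (cutpoints are midpoints between consecutive order
  statistics, which scans exactly the distinct partitions); the cutpoint
  maximizing the interaction Wald statistic is then tested as if
  prespecified. No selection correction is applied: the procedure's ~50%
  false-positive rate is the phenomenon under study. The 10% minimum is on
  the overall subgroup size, not per arm. The scan warm-starts each Newton
  fit from the neighbouring cutpoint's solution (the optimum is unique, so
  this changes nothing but speed).
* **Cox linear interaction** — Z, T, Z×T with continuous Z; Wald test of
  Z×T.
* **STEPP (sliding window)** — subjects ordered by z; windows of size
  round(n/5) advancing by round(n/10), the last window absorbing any
  remainder — nine windows at n = 250/500/1000. Per window, a
  treatment-only Cox fit gives β̂_j; heterogeneity around the all-data β̂ is
  Q = Σ_j (β̂_j − β̂)²/var(β̂_j). The published description names only "a
  test on homogeneity of the hazard ratio"; this inverse-variance weighted
  chi-square is our concrete choice, and the permutation reference makes
  the test exact regardless of that choice. The permutation scheme shuffles
  biomarker values against fixed (time, event, arm) tuples — 500
  permutations by default, add-one p estimator. Permuting z rather than
  treatment labels preserves the survival/treatment structure and targets
  exactly the effect-modification null; which variable the original STEPP
  permutation test shuffles is not specified in our source, so this is a
  recorded assumption. Windows with no events in an arm are dropped from Q
  in observed and permuted statistics alike.
* **MFPI** — fractional-polynomial transforms with powers from
  {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log; repeated FP2 powers add a log
  factor). FP2-flex1: the 36 FP2 pairs are ranked by the main-effects
  model's log partial likelihood; the winning pair is kept and the 2-df
  interaction LRT performed. FP1-flex3: the best FP1 power is selected
  separately in the null and interaction models and the two winners
  compared by a 1-df LRT. The df is 1 because both models carry T plus one
  z-term and differ by the single interaction coefficient; no
  selection-optimism correction is applied, and none is wanted — the ~10%
  type-I error of flex3 is a finding the package reproduces. The statistic
  is nonetheless always ≥ 0: the interaction-model maximum is at least the
  null winner's interaction fit, which nests it. Likelihood ties break
  toward smaller powers via fixed candidate ordering. z ∈ (0, 1) is
  strictly positive, so no origin shift is needed before transformation.
* **LPLB** — at each of the nine interior empirical deciles z_k, subjects
  are weighted by an Epanechnikov kernel K(u) = 0.75(1 − u²) with bandwidth
  h = 0.2 on the biomarker scale (with Z uniform on [0,1], scale- and
  fraction-based bandwidths nearly coincide; scale-based is our choice) and
  a weighted Cox fit with columns T and T·(z − z_k) — a first-order local
  expansion — yields the local log-HR β̂(z_k) and its se. The test statistic
  is M = max_k |β̂(z_k) − β̂_cox|/se(β̂(z_k)) with β̂_cox from the
  treatment-only Cox model. The null distribution is a model-based
  bootstrap under the fitted constant-effect model: event times are
  regenerated by inverse transform on the null fit's Breslow baseline
  cumulative hazard (each subject keeping its own z, arm, and relative
  risk); censoring times are drawn from the reverse Kaplan–Meier estimate
  of the censoring distribution, capped administratively at the largest
  observed time. Holding every subject's censoring time literally fixed is
  impossible — it is unobserved for subjects with events — so resampling
  the estimated censoring distribution is our realization of a
  residual-type bootstrap; its adequacy is judged by the reproduced
  type-I-error rates (≈5% under the null scenarios). Evaluation points
  whose local fit is degenerate are dropped from M symmetrically in
  observed and bootstrap statistics. 500 bootstrap samples by default,
  add-one p estimator.

## Study harness

`run_study` crosses scenarios × sample sizes × censoring rates × methods,
simulates `n_reps` trials per cell (1000 by default) and counts p < α
(α = 0.05; p exactly equal to α — possible on the discrete permutation
grid — counts as non-rejection). Rejection rates carry exact 95%
Clopper–Pearson intervals from beta quantiles. Per-replicate seeds are
spawned from the master seed keyed by cell coordinates, so results are
byte-identical across runs and independent of the worker count; per-cell
JSON files allow interrupted runs to resume.

## Numerical and scale choices

* Monte-Carlo sizes in the test suite follow the precision each check
  needs: non-resampling methods are checked at m = 1000 replicates;
  LPLB calibration at m = 200 with B = 200 bootstrap samples, and the
  Scenario-6 power ordering at m = 100/B = 200, where the compared rates
  differ by ~70 percentage points and small m suffices. `scripts/acceptance.py`
  uses m = 1000 throughout (m = 400 for FP2-flex1).
* Rate checks assert that the observed rejection count falls in the exact
  binomial 95% band implied by the published rate at the replicate count
  used — the natural tolerance for a Monte-Carlo quantity.
* Failed fits never raise inside a test procedure; they yield p = 1 and a
  `failed` flag, biasing every reported rate conservatively and visibly
  (failure counts are part of the study output).

## Known limitations

* The STEPP homogeneity statistic and the LPLB bootstrap realization are
  concrete choices where the source descriptions underdetermine the
  algorithm; both are validated against the published operating
  characteristics, not against the original implementations.
* The LPLB statistic is only approximately invariant to swapping arm
  labels (the local slope term breaks exact symmetry by a few percent).
* Only the single prespecified-biomarker setting is covered: no
  multiple-biomarker multiplicity handling, no subgroup selection or
  clinical-utility assessment downstream of detection, and no tail-oriented
  STEPP variant.
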