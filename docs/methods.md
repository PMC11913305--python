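# Methods

## Generative model and study conditions

All simulations draw populations of N = 100,000 independent units with

- X1 ~ Normal(3, 2.25) — the fully observed covariate,
- X2 ~ Normal(5, 4) — the auxiliary covariate subject to missingness,
- eps ~ Normal(0, sigma^2), sigma^2 in {1, 3, 5, 7, 9},

and the response Y = 0.5 + 1.0·X1 − 0.3·X2 + eps.  The three columns are
mutually independent; the error is drawn as a population column and travels
with each unit through sampling so that ranked-set selection operates on
complete triples.  Populations are regenerated per replication from the
replication's seed stream rather than stored: 300,000 normal draws cost
milliseconds and a fixture file would add nothing.

What the generator does *not* emulate: non-normal or skewed covariates,
heteroscedastic or correlated errors, more than two covariates, and any
missingness mechanism other than MCAR.  Passing tests therefore demonstrate
correctness of the estimators and harness under the stated normal/MCAR
conditions, not robustness of the methods on real data.

## Sampling designs

**SRS** draws n distinct rows uniformly.  Without-replacement sampling is
implemented by batch-redrawing colliding draws, which is equivalent to
sequential rejection sampling and exactly uniform over distinct index sets.

**RSS** uses, per cycle, `set_size` independent simple random sets of
`set_size` units each; set i contributes the unit with the i-th smallest
value of the ranking covariate (perfect ranking on true values).  The
default layout is one cycle of n sets of n units — the literal text-book
procedure, at a cost of n² draws per sample — configurable via
`RSSConfig(set_size, cycles)` with `set_size · cycles = n`.  Design
choices where the procedure is under-determined:

- ranking defaults to X2, the auxiliary that carries the quartile
  adjustment, and is exposed as `rank_on`;
- sets are drawn with replacement *between* sets (each set is an
  independent SRS), the standard RSS convention;
- ties in the ranking values break by stable sort, lowest draw position
  first;
- the last order position takes the maximum of its set (standard RSS).

**Multicollinearity screen.**  A sample is accepted when
|Pearson r(x1, x2)| < 0.6; otherwise it is redrawn, up to `max_tries`
(default 100), after which a screening error reports the last correlation.
Under the independent generative model the first draw passes in ≫ 99% of
cases, so the screen is effectively a guard against pathological draws at
small n.

## Missingness

Only X2 is masked.  The number of missing cells is round(n·pct), half away
from zero — every (n, pct) combination in the default grid is an exact
integer, the rounding rule only matters for user-supplied rates.  Positions
are uniform without replacement and independent of all data values (MCAR).
At least 4 complete rows must remain so that a listwise three-coefficient
fit stays estimable.

## The imputation pipeline

1. **Series-mean fill**: missing x2 cells take the mean of the observed x2
   values.
2. **OLS stage**: ordinary least squares of y on (1, x1, x2_filled) over
   all n rows (not complete cases), giving in-sample predictions ŷreg.
   The fit is a `numpy.linalg.lstsq` call; a rank-deficient design raises a
   numeric-domain error.
3. **Adjustment**: a single multiplicative factor per (sample, method)
   rescales ŷreg at the masked rows only; unmasked rows keep ŷreg.

The factor formulas are in the README and `imputers.py`.  Numeric and
interpretive choices:

- **The factor is applied once per masked prediction, not raised to the
  k-th power.**  The factor is index-free — it contains only sample-level
  means and quartiles — and a k-fold power would make predictions diverge
  with the number of missing cells, incompatible with the magnitudes the
  estimators are designed to produce.
- **x̄2n, the complete-column mean, is an oracle quantity.**  The simulator
  knows the pre-masking column and uses its mean.  On real data no complete
  column exists; the estimator then falls back to the mean of the filled
  column, which equals x̄2r and makes the factor exactly 1, unless the user
  supplies a reference mean (`complete_mean=` / `--complete-mean`).
- **Quartiles** are computed from the observed (non-missing) values of each
  covariate by linear interpolation at rank 1 + (n−1)p (the numpy default
  "linear" method); this convention is fixed so results reproduce
  bit-for-bit.  Known population quartiles can be supplied instead via
  `population_quartiles=`.
- **Each covariate uses its own quartile** in the multivariate families
  (q of x1 for the x1 term, q of x2 for the x2 term).
- Because x1 is never masked, its responding mean equals its full mean, the
  x1 ratio term is identically 1, and the multivariate ratio reduces to
  ε1 + ε2·f(x2).  This is asserted in the tests, not special-cased in the
  code.
- Non-positive shifted denominators raise a numeric-domain error rather
  than returning a sign-flipped factor; under the default generative model
  (means 3 and 5, positive quartiles) they do not occur in practice.

**Tuning constants.**  The defaults — chain exponent α = 0.90,
multivariate-ratio weights (ε1, ε2) = (0.90, 0.10), multivariate-chain
α = 0.10 and (ω1, ω2) = (0.10, 0.90) — are the constants reported as best
performers over the grid {0.1, 0.3, 0.5, 0.7, 0.9}.  `tune_constants`
re-runs that grid search (scoring candidates on shared replications,
minimising mean MSE) for users who want to re-derive or extend them; the
package never re-tunes silently.

## Evaluation harness

Per replication: draw population → screened sample under the scenario's
design → mask → fill/OLS/context once → per-method factor and predictions →
MSE and MAPE.  All methods share the sample and mask within a replication
(paired comparison); methods differing only in quartile share ŷreg
exactly.

- **MSE** = (1/n)·Σ(yᵢ − ŷᵢ)², **MAPE** = (100/n)·Σ|yᵢ − ŷᵢ|/|yᵢ|,
  both computed in-sample over all n rows.  MAPE is undefined when any
  yᵢ = 0 and is heavy-tailed here because E[Y] = 2 while
  Var[Y] ≈ 3.6 + σ², putting mass near zero; its simulated cell values are
  accordingly unstable and are covered by arithmetic examples and
  invariants rather than pinned numerically.
- **Listwise control**: OLS fit on complete cases, scored on complete
  cases — prediction at rows with missing x2 is impossible without
  imputation, so no other evaluation set is well defined for it.
- **Seeding**: replication r of a scenario uses
  `SeedSequence(scenario.seed, spawn_key=(r,))`, so replications are
  independent, reproducible and order-insensitive (scenarios can be run in
  parallel, `--jobs`).
- **Scenario means** carry Monte-Carlo standard errors
  (sd over replications / √reps).

Summary tables follow the study's class structure: sample-size classes
Small {20, 40}, Middle {60, 80}, Large {100, 120}, Huge {200, 500} and
error-variance classes Small {1}, Middle {3, 5}, Large {7, 9}.
`best_method_summary` reports the argmin method per (design, variance
class, size class, metric), averaging over the member cells and reporting
ties jointly; `design_win_counts` counts, per (sigma^2, size class) block
of 96 cells (2 sizes × 6 rates × 8 methods), how often the RSS mean metric
is strictly below the SRS one.

## Problem sizes used by the shipped checks

The full-scale checks run 1,000 replications at n = 500 with 5%
missingness — the most tightly pinned cells, where the mean MSE is
determined by the generative variance to within a fraction of a percent
(Monte-Carlo standard error ≈ 0.002 at sigma^2 = 1).  Property and unit
tests use small populations (2,000–5,000 units) and samples (n = 8–60),
where every quantity can be checked against first-principles
re-computation.  The default CLI grid (480 cells × 8 methods × 1,000
replications) reproduces the whole study and is sized for an unattended
run, not for the test suite.

## Known limitations

- In-sample evaluation over all n rows is one reading of an
  under-specified scoring protocol; reported mean MSEs track the expected
  in-sample level sigma^2·(n−4)/n plus a small fill-induced inflation, and
  agree with the published reference cells to within ~1–2% at n = 500
  rather than exactly.
- The adjustment factor helps only insofar as the responding mean drifts
  from the complete mean; at 5% missingness the correction is tiny, and
  all eight methods perform within Monte-Carlo noise of each other.
- No variance estimation for the population-mean estimators, no
  MAR/MNAR mechanisms, no imputation of x1 or y, no multiple imputation.
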