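# Methods

## Model and procedure

BNNPT (bagging nearest-neighbor prediction test) tests the null hypothesis
that two paired continuous variables X and Y are independent, against the
alternative that Y is predictable from X. It is a permutation test whose
kernel is a bagged 1-nearest-neighbor regressor:

1. **Neighborhood structure.** For each point *i* and each of *b* bags, draw
   `mtry` candidate indices uniformly without replacement from the other
   N − 1 points and record the candidate whose X value is closest to x_i
   (ties in |x_k − x_i| broken uniformly at random). The result is an
   N × b integer matrix depending on X, b, mtry and the seed only — never
   on Y. Its diagonal-free, row-stochastic weight form W (W_ik = fraction
   of bags in which k is i's neighbor) gives the out-of-bag prediction
   H = W·Y.
2. **Statistic.** SE = ‖H − Y‖₂. Small SE means Y is well predicted by its
   X-neighbors. Any monotone transform of SE (e.g. the squared norm) yields
   the same permutation p-value.
3. **Permutation null.** Holding the structure fixed, recompute SE for B
   uniform random permutations Y′ of Y and report the fraction with
   SE(Y′) ≤ SE(Y) (non-strict). The evaluation uses the identity
   SE(y′) = ‖(W − I) y′‖, mathematically equal to the gather-and-average
   form and verified against it in the tests to 1e-10 relative tolerance.

Subsampling rather than using all N − 1 candidates (mtry ≪ N) decorrelates
bags and acts as regularisation; the test behaves well with the default
mtry = round(√N) and is insensitive to b beyond a few hundred.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `bags` b | 256 | number of bags; chosen for computing efficiency, results are stable beyond ~100 |
| `mtry` m | round(√N), min 1 | candidates per bag; √N balances neighbor locality against bag diversity (N = 50 → 7) |
| `permutations` B | 1000 | Monte-Carlo resolution 1/B; 1000 suffices at α = 0.05, raise for small thresholds |
| `alpha` | 0.05 | nominal level used by callers that threshold p |
| `seed` | required | master seed; split into one substream for structure building and one for permutations, so results are independent of any execution-order change |
| `p_estimator` | `add_one` | (count + 1)/(B + 1) is never zero and is a valid p-value; `raw` (count/B) matches implementations that can report exactly 0 |
| `replace` | False | draw bag candidates with replacement instead (sensitivity checks only; duplicates cannot change the argmin, only its distribution) |

## Numerical and design choices

- **Bag sampling without replacement** from the other N − 1 points is the
  default: it guarantees the no-self-neighbor constraint by construction and
  maximises candidate diversity. Sampling is implemented by ranking i.i.d.
  uniform keys, which is an exact uniform without-replacement draw.
- **X-ties** are broken uniformly at random through the same seeded RNG, so
  discrete, genotype-like X values carry no index-order bias.
- **Constant X** degenerates to uniformly random neighbors; the test stays
  defined and null-calibrated (it just has no power), so a warning is logged
  instead of an error.
- **Inequality direction** is non-strict (SE_random ≤ SE_observed), so
  degenerate data (constant Y) give p = 1 rather than p = 0.
- **Exhaustive oracle.** For N ≤ 8 the exact permutation p-value over all
  N! permutations is available and is used in the tests to validate the
  Monte-Carlo estimator (agreement within 3 binomial standard errors at
  B = 50,000).
- **Batch seeds** derive from the master seed and a CRC32 hash of the
  feature id, making batch results invariant to feature order.
- **Batch direction.** Each feature row is the predictor X and the phenotype
  the response Y (the test is asymmetric); `swap` reverses this. Binary 0/1
  phenotypes are accepted with a logged warning — the method assumes a
  continuous response.
- Multiple testing uses Bonferroni only (α/m in full precision); FDR is out
  of scope.

## Comparators

Pearson, Spearman and Kendall delegate to scipy.stats (two-sided t-based
p-values for the correlation tests, tau-b with scipy's exact-or-asymptotic
policy for Kendall). Distance correlation (double-centered distance
matrices) and Hoeffding's D (classical rank form with midrank tie
corrections, scaled so tie-free monotone data give D = 1) are implemented
here with Monte-Carlo permutation p-values, since no vetted implementation
is available in the dependency set; both are cross-checked in the tests
against independent brute-force formulations. Hoeffding's D targets
continuous margins and can misbehave under heavy discreteness. Rank-based
statistics are invariant to strictly monotone marginal transforms, and this
is asserted as a property test. MIC and CANOVA are not implemented; power
tables treat the method label as free-form so externally computed columns
can be merged.

## Simulation study

`Scenario` draws x ~ Uniform(−1, 1) and sets y = f(x) + ε with
ε ~ N(0, σ²), for f among: 0 (the null), x, 0.5(x+1)², sin πx, sin 3πx,
cos πx, cos 2πx, cos 3πx. Defaults: N = 50, σ² = 1, 1000 replicates,
α = 0.05. "Noise variance" is the variance, not the standard deviation.
Each replicate's RNG is seeded from (master_seed, replicate_index) alone, so
datasets are regenerable in isolation and *shared across methods* — method
comparisons are paired, which reduces comparison variance. The rejection
rate on the null scenario estimates the type-I error; on any other scenario
it estimates power, always accompanied by the binomial Monte-Carlo standard
error √(r(1−r)/n_sims).

What the generator does *not* emulate: heteroscedastic or non-Gaussian
noise, tied or discrete X, outliers, and sample-size regimes other than
those configured. A green simulation test therefore establishes calibration
and power under clean continuous data at the stated N and σ², not
robustness beyond it.

## Known limitations

- Univariate X and Y only; no covariate adjustment (a residual-on-covariates
  pre-step is possible but not provided).
- Monte-Carlo p-values have resolution 1/B (add-one: 1/(B+1)); genome-scale
  screens at thresholds like 2.4e-06 need B ≥ ~10⁷ to resolve the cutoff.
- The permutation loop is O(b·N·mtry + B·N²) per test; batch screens of
  tens of thousands of features at large B are compute-bound and should be
  sharded externally (results are seed-stable under any sharding).
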