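# Methods

## The CE-FDH necessity effect

Given n paired observations (x_i, y_i), the **peers** are the observations
not weakly dominated toward the upper left: (x_i, y_i) is a peer iff no other
observation (x_j, y_j) has x_j ≤ x_i and y_j ≥ y_i with at least one
inequality strict. Sorted by x, the peers are strictly increasing in both
coordinates, and the CE-FDH ceiling is the step function
ceiling(x) = max{y_i : peer i with x_i ≤ x}. The ceiling zone

    C = Σ_{i=1..k} (x_{i+1} − x_i)(Y_max − y_i),  with x_{k+1} := X_max,

is the exact area between the ceiling and y = Y_max over [X_min, X_max]; the
scope is S = (X_max − X_min)(Y_max − Y_min), and the necessity effect is
d = C/S. Because some observation always attains X_min, the first peer sits
at x = X_min and no boundary special case is needed.

Choices made where the construction admits variants:

- **Ties.** Weak dominance handles discrete (e.g. Likert) data: among points
  sharing an x only the maximal y can be a peer, so the ceiling is a
  well-defined non-decreasing step function. Duplicated points keep one
  representative.
- **Exact comparisons.** Dominance uses exact floating-point comparison, no
  epsilon: inputs are data, not optimizer iterates. Users should not
  pre-round their data expecting fuzzy tie handling.
- **Degenerate scope.** If all x or all y coincide the normalizer S is zero
  and d is undefined; this raises `DegenerateScopeError` naming the collapsed
  dimension rather than returning d = 0, which would silently assert "no
  necessity" on evidence that cannot distinguish anything.
- d is computed as C/S and clipped to [0, 1] only to remove last-bit
  floating-point noise; both invariants (d ∈ [0, 1], corner occupancy ⇒
  d = 0) hold exactly in the construction.

## Permutation test

The null draw permutes y uniformly at random against fixed x, destroying the
dependence while preserving both marginals (and hence the scope), and
recomputes d. The p-value uses the add-one convention
p = (1 + #{d_null ≥ d_obs}) / (1 + reps), a finite-sample-valid estimator
that can never be exactly zero. The number of replicates and the p-value
convention are this package's declared choices; defaults are reps = 1000.
Because CE-FDH effects are discrete over permutations, ties make the test
conservative at worst.

## Range of spuriousness

The spuriousness check treats "X and Y are merely correlated" as the null.
For a study with sample size n and Pearson correlation r it generates `reps`
(default 1000) datasets of n pairs from a standard bivariate normal — zero
means, unit variances, population correlation exactly r, applied through the
Cholesky factor of the 2×2 correlation matrix — scores each with CE-FDH, and
takes the nonparametric percentile interval of the `reps` effects at level
`ci_level` (default 0.95, i.e. the 2.5th and 97.5th percentiles). An observed
effect is classified `below`, `within` or `above` the interval; equality with
a bound counts as `within`, matching the reading that only effects strictly
above the range support a necessity claim.

- **Quantile estimator:** linear interpolation of order statistics (numpy's
  default), exposed as `SpuriousnessConfig.quantile_method`. At reps = 1000
  the estimator choice moves the bounds by well under 0.01.
- **Fixed population r:** each replicate uses the same population correlation;
  r is a parameter of the null, not resampled per replicate. The sample
  correlation of each replicate then varies naturally around r.
- **Affine invariance** of d means the standard-normal marginals are without
  loss of generality within the normal family: any means and variances give
  the same d distribution.

Since d is invariant to positive affine maps of either axis, the bivariate
normal null covers any elliptical rescaling of real data; it does **not**
emulate discreteness (Likert scales), skewness, heavy tails, floor/ceiling
effects of bounded instruments, or measurement error. A verdict on real data
is therefore a statement relative to this continuous-normal null, and the
simulated bounds can differ from what, say, a discretized null would give.
Non-normal null families are a natural extension but are out of scope here.

## Reproducibility

Every stochastic operation takes a single integer seed. Replicate-level
streams are spawned from `numpy.random.SeedSequence(seed)` per replicate
index, so results are bit-reproducible and independent of any future
parallelisation of the replicate loop. Identical configurations give
bit-identical results; different seeds move the reps = 1000 percentile
bounds by a few hundredths (the quantile standard error at that replicate
count).

## Problem sizes used in the test suite

Oracle checks compare the analytic ceiling zone against brute-force
column-wise grid integration (20 000 columns; error bound n·Δx·Y-range) and
the peer set against an O(n²) dominance scan, on hundreds of random samples
of n ≤ 50. The permutation p-value is validated against exhaustive
enumeration of all 4! permutations of an n = 4 sample, and its nominal level
under independence is checked over a few hundred simulated datasets at
reduced replicate counts. The headline simulation (n = 340, reps = 1000) runs
in seconds and is repeated across several seeds.

## Limitations

- CE-FDH only; ceiling-regression variants (e.g. CR-FDH), multi-condition
  bottleneck analyses and plotting are out of scope.
- The spuriousness verdict compares against correlation alone; it says
  nothing about *why* X and Y are correlated (e.g. confounding).
- The CLI ingests delimited text with period decimal separators only, for
  locale-independent reproducibility.
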