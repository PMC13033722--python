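# ncarigor

Necessary condition analysis (NCA) with a built-in spuriousness check.

NCA asks whether a condition X is *necessary* for an outcome Y: if it is, the
upper-left corner of the X–Y scatter (low X, high Y) should be empty. The
standard effect size is estimated with the **ceiling envelopment with free
disposal hull (CE-FDH)** technique: a non-decreasing step function through the
upper-left frontier points ("peers") of the data. With scope
S = (X_max − X_min) × (Y_max − Y_min) and ceiling zone C (the area between the
step ceiling and y = Y_max), the necessity effect is

    d = C / S ∈ [0, 1].

A nonzero d, however, does not establish necessity: an ordinary linear
correlation between X and Y already empties part of that corner. This package
therefore also computes the **range of spuriousness** — the nonparametric 95%
percentile interval of d across many (default 1000) synthetic bivariate-normal
datasets sharing only the sample size n and the Pearson correlation r of the
real data. An observed effect at or below the upper bound of this interval is
explainable by the correlation alone; only an effect *above* the range
supports a necessity claim. A permutation test of d (y shuffled against fixed
x, add-one p-value) is included for the conventional "is d > 0" question.

The package is aimed at applied researchers — in mental-health epidemiology
and beyond — who want to run or scrutinize NCA claims from either raw data or
just the published summary numbers (n, r, d).

## Worked example

The four points (1,1), (2,3), (3,2), (4,4) have peers (1,1), (2,3), (4,4),
ceiling zone C = (2−1)(4−1) + (4−2)(4−3) = 5 and scope S = 3 × 3 = 9:

```python
from ncarigor import NecessityAnalysis

res = NecessityAnalysis([1, 2, 3, 4], [1, 3, 2, 4]).fit()
print(res.summary())
```

```
Necessary Condition Analysis (CE-FDH)
======================================
No. observations    4
No. peers           3
Ceiling zone (C)    5.0000
Scope (S)           9.0000
Necessity effect d  0.5556
Pearson r           0.8000
```

So 55.6% of the scope rectangle lies above the ceiling. `res.permutation_test(
reps, seed)` and `res.spuriousness(reps, ci_level, seed)` hang off the fitted
results; `NecessityAnalysis.from_dataframe(df, x="pb", y="si")` builds the
model from a DataFrame.

The same analyses are available from the shell. Scrutinizing a published
claim needs only the summary numbers — here a study of n = 340 reporting
r = 0.75 and an observed necessity effect d = 0.26:

```sh
$ ncarigor spuriousness --n 340 --r 0.75 --d-obs 0.26 --seed 1
Range of spuriousness (CE-FDH under bivariate-normal null)
  n         340
  r         0.75
  reps      1000
  seed      1
  95% range 0.22-0.43
  d observed 0.26 -> within
```

The verdict `within` means d = 0.26 is no stronger than what a correlation of
0.75 alone would produce at this sample size, so the data do not support a
necessity interpretation. `ncarigor effect TABLE --x COL --y COL` and
`ncarigor test TABLE ... --reps R --seed S` run the estimator and the
permutation test on a CSV/TSV table; `--json` emits a machine-readable report
carrying full precision and the seed.

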