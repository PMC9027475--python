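# flimpute

Fast linear imputation of expression profiles by simplex-constrained
least squares.

## The problem

High-dimensional expression profiling (miRNA panels, bulk and
single-cell transcriptomics) routinely produces profiles with missing
entries — technical zeros, dropouts, or features simply not measured on
a given platform. A classifier trained on complete reference data
cannot be applied to such profiles without either retraining or filling
the gaps. Naive choices degrade downstream analysis: imputing zeros
destroys classification accuracy once more than ~10% of dimensions are
missing, and unconstrained regression overfits badly when most of the
profile is gone.

`flimpute` completes a test profile **x** with missing entries as a
convex combination of complete reference (training) profiles. With
training matrix **A** (samples × features), known-feature index set *K*
and missing set *M*, the weights solve

```
min_w || A_K' w − x_K ||²   subject to   w ≥ 0,  Σᵢ wᵢ = 1,
```

and the completion is `x̂_M = A_M' w`. Because the weights lie on the
probability simplex, every imputed value is a convex combination of
observed reference values and therefore lies inside the per-feature
range of the training data — the method cannot extrapolate outside the
reference envelope, which is what makes it robust at extreme
missingness. The sum-to-one condition is enforced inside the
least-squares objective itself (a stiff constraint row appended to the
system), so nonnegative least squares and weight normalisation happen
in a single solve, performed by an active-set restarted conjugate-
gradient least-squares (nonnegative CGLS) routine. The method is
nonparametric: there is nothing to tune per dataset.

The package also ships, for benchmarking against the same interface:

* **baselines** — zero, feature-mean, and unconstrained minimum-norm
  regression imputation;
* **comparators** — simplified versions of two literature schemes:
  lasso neighbour selection + box-constrained regression
  (`viper_like`), and spectral clustering + nonnegative regression
  (`scimpute_like`);
* **synthdata** — seeded generators for stroke-rendered 28×28
  handwritten-digit images, block-correlated multivariate-normal
  "expression" matrices, and uniform per-sample missingness masks;
* **evaluation** — the classification-retention harness: train a
  softmax (multinomial logistic) classifier on complete data, sweep a
  grid of missing fractions, and record AUC/ACC/F1 plus per-sample
  relative imputation errors (ε_μ, ε_σ, ε_M) and per-profile wall
  times (t_μ, t_σ, t_max).

## Worked example

```python
import numpy as np
import flimpute as fl

# complete reference matrix: 200 correlated "expression" profiles
train = fl.gen_mvn(n=200, p=200, block_size=20, within_block_corr=0.8,
                   seed=0, class_shift=2.0)

# held-out profiles with 70% of their features missing
test = fl.gen_mvn(n=50, p=200, block_size=20, within_block_corr=0.8,
                  seed=1, class_shift=2.0)
profiles, truth = fl.apply_missingness(test, fl.MissingnessSpec(0.70, seed=7))

res = fl.fli_impute(train, profiles[0])
w = res.weights.w
eps = np.linalg.norm(res.completed - truth.values[0]) / np.linalg.norm(truth.values[0])
print(f"weights: min {w.min():.3f}, sum {w.sum():.6f}, "
      f"support {np.count_nonzero(w)}")
print(f"relative imputation error at 70% missing: {eps:.3f}")
```

prints

```
weights: min 0.000, sum 1.000000, support 36
relative imputation error at 70% missing: 0.380
```

The weights are nonnegative, sum to one, and concentrate on a subset of
reference profiles (36 of 200 here); the completed profile reproduces
the hidden 140 of 200 features with a relative ℓ2 error of 0.38,
against 0.85 (≈ √0.70) for imputing zeros on the same standardised
profile.

The same pipeline is available from the shell:

```sh
flimpute simulate mvn --n 200 --seed 0 --out ref/
flimpute impute --train ref/matrix.csv --test patients.csv --method fli --out done/
flimpute sweep --train train.csv --test test.csv \
    --methods fli,mean,zero --fractions 0.25,0.5,0.75 --out sweep/
```

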