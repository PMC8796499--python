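# Methods

## The anonymisation model

`detanon` implements a deterministic microaggregation scheme for mixed
continuous/categorical microdata. The premise: categorical variables act as
quasi-identifiers and are protected by *k-anonymity* (every observed
combination of levels must occur at least k times); continuous variables
carry the fine-grained, potentially disclosive information and are
perturbed, while their spatial statistics are preserved as far as possible.

Given a table with continuous block X (n × p_c, p_c ≥ 1) and categorical
block C, and a single integer parameter k:

1. **Standardisation.** Each continuous column is z-scored:
   z_j = (x_j − μ_j)/s_j with the sample mean μ_j and sample standard
   deviation s_j (denominator n − 1). This puts all variables on a common
   scale so the Euclidean metric in step 3 is not dominated by units.
2. **Stratification + k-anonymity.** Rows are partitioned by every
   *observed* combination of the categorical levels (unobserved
   combinations are not materialised; with no categorical columns the whole
   table is one stratum). Each stratum must contain at least k rows; see
   *Small strata* below.
3. **Neighbour search.** Within each stratum, each record's k − 1 nearest
   neighbours are found under Euclidean distance on the standardised scale.
   The neighbour set of record i is {i} ∪ (its k − 1 nearest other rows).
4. **Centroid replacement.** Record i's standardised vector is replaced by
   the per-dimension mean of its neighbour set; strata are pooled back in
   the original row order. Averaging shrinks spread, so the masked columns
   have sd < 1.
5. **Re-scaling and re-centring.** Each masked column is multiplied by
   s_j / sd(masked_j) and shifted by μ_j — computed on the whole pooled
   dataset, never per stratum. The released column therefore has *exactly*
   the original sample sd, and approximately the original mean.

The procedure has no random element: identical input and configuration give
bit-identical output, which lets custodians audit a release and prevents
averaging attacks over repeated noisy releases.

### Design choices where the procedure is genuinely open

- **Sample vs population sd.** Sample sd (n − 1) throughout. Only the ratio
  s_j/sd(masked_j) and μ_j enter the output, so the convention mainly needs
  to be consistent; the sample convention matches how analysts summarise
  observed data.
- **Tie-breaking.** Equidistant neighbours (including exact duplicates) are
  ranked by ascending row index. Any fixed rule would do; a deterministic
  one is required for the headline reproducibility guarantee. The record
  itself is always a member of its own neighbour set, even when duplicates
  of it exist at distance zero.
- **Mean after step 5.** The literal recipe (scale, then add the original
  mean) is kept. Because the centroids' grand mean is not exactly zero, the
  released mean differs from the original in the third–fourth decimal
  relative to sd. No extra re-centring is applied: exactness in the sd and
  determinism are the stated guarantees, the mean is approximate.
- **Order of operations with preprocessing.** The k-anonymity check runs
  after imputation/complete-case filtering (dropping rows changes stratum
  sizes). If suppression removes rows, standardisation parameters are
  computed on the surviving rows, so sd preservation holds for the table
  actually released.
- **Small strata.** Default policy is to *error*; alternatives are
  suppression (drop the violating strata's rows) or a user-supplied merge
  map of category levels (re-checked afterwards). No automatic
  generalisation-lattice search is attempted — choosing semantically
  sensible coarser categories is the custodian's call.
- **Zero-variance continuous columns** are rejected at standardisation by
  name rather than passed through silently: a constant column cannot be
  perturbed by this method and usually signals a mis-declared role.
- **Choice of k.** k ≥ 3 is recommended for release: with k = 2, an
  attacker knowing a centroid plus the pair's mean and variance could
  reconstruct exact values. k = 1 (identity) is allowed for testing, and
  k equal to the smallest stratum size collapses that stratum onto a single
  centroid — the extreme of information loss.

## Utility-loss metrics

- **Global U.** The original and anonymised tables are stacked; an
  indicator (1 = anonymised) is regressed on all variables by
  maximum-likelihood logistic regression, categoricals dummy-encoded,
  main effects only; U = (1/N) Σ (p̂_i − ½)² with N = 2n. U ∈ [0, ¼]:
  0 when the halves are indistinguishable, ¼ when separable. The
  main-effects specification is the simplest faithful reading of
  "regressed on all the variables"; richer propensity specifications
  (interactions, polynomials) are compatible with the framework but not the
  default. If the fit separates perfectly the MLE does not exist; the
  implementation then reports the supremum ¼ with a `SeparationWarning`
  instead of failing, because separation *is* the answer to the question U
  asks.
- **Per-variable δ.** δ_x = mean((x_or − x_an)²) / Var(x_or) with the
  sample variance (n − 1), consistent with the anonymiser's convention.
  δ = 0 iff the variable is untouched; δ = 0.4 reads "40 % of the
  anonymised variable's variability was introduced by anonymisation".
  δ is invariant under a common affine map of both vectors.
- **Analysis-specific d.** The analyst's intended regression (OLS or
  logistic, treatment-coded categoricals) is fitted to both tables;
  d = |β̂_or − β̂_an| / SE(β̂_or) per coefficient, plus a check that the two
  95 % Wald intervals intersect. Intervals are closed: touching endpoints
  count as overlap (the boundary case is measure-zero and the generous
  convention avoids a spurious alarm from rounding).

## Disclosure-risk metrics

Squared Mahalanobis distances RMD²_i of the original rows from the
multivariate centre are computed with the Minimum Covariance Determinant
estimator (sklearn's `MinCovDet`, default coverage, fixed seed 42 so robust
mode is deterministic); a classical mean/covariance mode exists for
hand-checkable examples and for n close to p. Then:

- **risk1** = proportion of rows whose anonymised vector lies inside the
  box ∏_j [x_ij − w1·RMD²_i, x_ij + w1·RMD²_i] around their original
  vector. "Inside" means inside on *every* dimension, with closed
  endpoints; the half-width is the same in every dimension and is computed
  on the released data scale (after step 5), matching how the metric is
  used on real applications. risk1 is monotone non-decreasing in w1 and
  independent of w2 and m.
- **risk2** = proportion of rows that are risky *and* have fewer than m
  other anonymised rows within Euclidean distance w2 of their anonymised
  vector ("other" excludes the row itself; duplicates count). risk2 ≤ risk1
  by construction and is monotone non-increasing in w2.

Defaults w1 = 0.01, w2 = 0.05 follow the reference implementation of this
metric in the R `sdcMicro` package (`dRiskRMD`); m is never stated there or
in the applications we mirror, so the package defaults to the strictest
value m = 1 and exposes it. Whether the reference computes distances on raw
or standardised data is likewise unspecified; this implementation uses the
data scale supplied by the caller and records that as its own convention.
Exact risky/unsafe counts on a given dataset can therefore differ from the
reference when the robust-estimator internals differ, even when the
proportions agree closely.

## The synthetic cohort generator

`simulate_cohort` emulates a mid-century British birth-cohort extract: four
continuous biomarkers (fasting glucose, HDL cholesterol, height, weight)
and two binary variables (sex, current smoking) whose four combinations
form strata with proportions 40.6 / 9.2 / 38.6 / 11.6 %. Stratum sizes are
integer-apportioned by largest remainder — floor(n·p) plus one unit to the
largest fractional remainders — which reproduces the published size vectors
(203, 46, 193, 58) at n = 500 and (20, 5, 19, 6) at n = 50 exactly and
never deviates from n·p by a full unit.

Continuous variables use the Fleishman power method: Y = a + bZ + cZ² + dZ³
with a = −c and (b, c, d) solving the standard moment system for target
skewness γ₁ and *excess* kurtosis γ₂ (normal = 0 — stated prominently
because the system differs by a constant under the other convention).
The system is solved numerically from the normal solution (1, 0, 0);
infeasible pairs (e.g. γ₂ = −3) fail with a residual check. Correlated
variables draw the underlying normals at the Vale–Maurelli intermediate
correlation, the real root in [−1, 1] of
ρ = r(b_i b_j + 3b_i d_j + 3d_i b_j + 9d_i d_j) + r²·2c_i c_j + r³·6d_i d_j.
A non-positive-definite intermediate matrix is an error (no silent
nearest-PD repair). Each stratum is simulated independently from seeds
spawned off the config seed (`numpy` `SeedSequence`), so results are
reproducible end-to-end and per-stratum moment targets can differ if
configured.

The default moment and correlation targets in `birth_cohort_config` are
**synthetic placeholders** at physiologically plausible values (e.g.
glucose: mean 5.4 mmol/L, sd 0.9, skewness 1.5, excess kurtosis 4). The
real cohort's moments are restricted data and are not reproduced; only the
stratum proportions are taken from published counts. Consequently the
sensitivity analyses reproduce the *monotone trends* of the published
curves, not their levels, and nothing here validates behaviour on features
the generator lacks: measurement error structure, missingness mechanisms,
within-stratum correlation differences, or heavy categorical cardinality.

## Sensitivity-analysis harness

`sweep_k` anonymises the same `reps` simulated cohorts (n = 500 by
default) at each k in the grid; `sweep_n` fixes k = 5 and varies n. Each
replicate is scored with U, per-variable δ, per-coefficient d (a linear
model of the first continuous variable on the others plus stratum
indicators — a stand-in for the analyst's model, chosen because the sweeps
must compute d without a prescribed analysis), risk1 and risk2; means and
standard deviations across replicates are reported. Default `reps` is 20 —
enough for stable trend estimates at interactive speed — with 100 available
for publication-grade error bars. Reusing the same replicate cohorts across
k values pairs the comparisons and removes simulation noise from the trend.

Observed behaviour (computed by the test suite and acceptance script, not
asserted from theory): mean U rises strictly with k and falls with n; mean
risk1 falls with k and rises with n. At the default w1 = 0.01 the risk1
levels on the synthetic cohort are very small (fractions of a percent), so
the risk trends are detectable but near the floor; larger w1 values show
the monotonicity more vividly (see `examples/03_disclosure_risk.py`).

## The Titanic worked example

`replicate_titanic` expects the public Kaggle training table (891 rows, 12
columns; https://www.kaggle.com/c/titanic/data — a login is required, so
the file is not redistributed here). Preprocessing: drop Ticket, Cabin,
Embarked and the direct identifier Name; impute the 177 missing ages with
the median of the 714 observed; recode SibSp + ParCh > 0 into a binary
Family indicator. Stratification uses Pclass × Sex × Family (12 observed
strata, smallest 32) — the sensitive outcome Survived is deliberately kept
out of the quasi-identifier set, though it still enters the propensity
model and the survival regression. Age and Fare are anonymised with k = 3,
and `Survived ~ Pclass + Sex + Age + Fare + Family` is fitted to both
tables. The corresponding tests assert the published preprocessing counts,
the original-data coefficients to ±0.01, the published utility-loss levels,
and risk1/risk2 near their published values (exact flagged-row counts
depend on unpublished robust-estimator settings and are not asserted).

## Numerical notes

- Neighbour search is exact brute force per stratum (O(n_s²) distances);
  at the package's intended scales (strata of 10³–10⁴ rows) this is both
  fast and free of approximation, and it makes the tie-break rule easy to
  guarantee. A tree-based search would have to replicate the stable
  ordering to preserve determinism.
- A "constant" masked column is detected with tolerance 1e−12 relative to
  the column's magnitude (floating-point dust, not signal) and reported as
  "k too large for the stratum structure".
- CSV output serialises floats in shortest round-trip representation, so
  write → read preserves values bit-for-bit and determinism survives I/O.
- Logistic fits use `statsmodels` Newton MLE; non-convergence that is not
  perfect separation raises with diagnostics rather than returning a
  half-converged U.
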