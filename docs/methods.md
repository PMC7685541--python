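# Methods

This note documents the statistical procedures the package implements,
the defaults it ships, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The problem

Omics biomarker studies need two linked answers: *which* features are
robustly associated with an outcome, and *how many samples* a follow-up
study needs to confirm a candidate. The package couples a
random-forest stability-selection engine (module 1) with a
simulation-based power engine that preserves the input correlation
structure (module 2).

## 2. Benchmark simulation (`forestpower.simdata`)

Six latent variables `x_1..x_6` are drawn i.i.d. from either U(0,1)
(`uniform01`) or the standard normal (`standard_normal`). Each latent
spawns a correlated group of `group_size = 10` predictors

    V_i^(j) = x_i + (0.01 + 0.5 (j-1)/(group_size-1)) * eps,
    eps ~ N(0, 0.3),  j = 1..10,

so correlation with the latent (and between group members) decays in
`j`; the first member is almost a copy of the latent (coefficient 0.01).
Remaining predictors up to `p_total` are i.i.d. draws of the base
distribution. The continuous outcome is

    y = 0.25 exp(4 x_1) + 4 / (1 + exp(-20 (x_2 - 0.5))) + 3 x_3
        + N(0, 0.2),

so only groups 1-3 are informative (with decreasing strength), groups
4-6 are correlated decoys and everything else is noise; per-variable
truth labels record this. For classification the outcome is split at
its mean for the uniform variant (the exp term skews y right, so the
below-mean class is the larger one) and at its median for the normal
variant (where a mean split would be extremely unbalanced because the
exp term is heavy-tailed under normal latents). Defaults are 200
observations and 5000 predictors; everything is reproducible from the
seed.

The denominator in the noise coefficient is read as `group_size - 1`,
so the coefficient runs 0.01 (j=1) to 0.51 (j=10); `N(0, s)` is read as
(mean, standard deviation). Both are configurable.

What the generator does *not* emulate: measurement batch effects,
missingness, heteroscedastic noise, non-linear inter-feature
dependencies beyond the shared latent, or realistic omics marginals.
Passing tests on this benchmark demonstrate that the selectors recover
a known correlated-block signal at the stated sample sizes — not that
they would behave identically on any particular real assay.

## 3. Forest engine (`forestpower.rf`)

Tree induction is scikit-learn's `RandomForestRegressor`/`Classifier`
(bootstrap resampling, `n_trees` default 500, `min_node_size` 1 for
classification / 5 for regression). `mtry` defaults to `floor(sqrt(p))`
(classification) and `max(p/3, 1)` (regression); the tuning helper
searches `{sqrt(p)/2, sqrt(p), 2 sqrt(p)}` or `{p/10, p/3, p/2}` and
breaks OOB-loss ties toward smaller `mtry`, then fewer trees, so tuning
is deterministic.

Variable importance is **unscaled out-of-bag permutation importance**
(mean decrease in accuracy / mean increase in MSE), not impurity
importance. Because scikit-learn does not expose it, it is computed
in-repo: for every tree, prediction loss on that tree's OOB samples is
compared with the loss after permuting one feature's OOB values at a
time; only features used by the tree's splits are traversed (others
contribute exactly zero) and the per-tree increases are averaged over
all trees. The traversal is a numba kernel validated in the tests
against explicit permutation plus `sklearn` tree prediction. OOB
predictions are aggregated per sample across the trees that did not see
it; `%Var explained = 100 (1 - OOB MSE / Var(y))` (sample variance,
ddof 1) and may be negative for worse-than-mean models.

## 4. Selection algorithms (`forestpower.selectors`)

**Boruta.** Each run appends a column-permuted "shadow" copy of every
still-kept variable (padded to at least five shadows) and fits a forest
on the doubled matrix. A variable scores a *hit* when its importance
exceeds the best shadow's. After each run, one-sided binomial tests on
the hit count (success probability 0.5), Bonferroni-adjusted across the
variables still undecided, confirm or reject at level `alpha = 0.05`;
rejected variables and all shadows are dropped before the next run.
The loop ends when everything is decided or after `max_runs = 100`
runs; variables still tentative are *not* selected. Shadows are drawn
for confirmed as well as undecided variables (the reference behaviour;
it only strengthens the null), while tests concern undecided ones only.

**Outcome-permutation selection.** Observed importance per variable is
compared with its own null distribution from forests refit after
permuting the outcome `n_perm` times (default 1000; scaled down in
tests): `p = (1 + #{null >= observed}) / (n_perm + 1)`, so p > 0 always.
`perm_raw` selects `p < 0.05`; `perm_corrected` first applies
Benjamini-Hochberg, so its selection is a subset of the raw one on
shared null draws. A pooled-null variant (all variables' nulls merged)
is available behind a flag; per-variable nulls are the default. A
model-level analogue (`model_permutation_test`) compares percent
variance explained (or OOB accuracy) against outcome-permuted refits.

**Recursive feature elimination.** A forest is fit, the OOB loss and
its standard error recorded, and `ceil(0.2 * p_current)` variables with
the smallest importance are dropped; this repeats down to a single
variable. The selected subset is the *smallest* whose loss is within
`se_rule` (default 1.0) standard errors of the minimum; `se_rule = 0`
takes the strict minimum. The importance ranking is computed once on
the initial fit and reused (the reference implementation's default);
`recompute_importance=True` re-ranks each step. The classification SE
is the binomial `sqrt(e(1-e)/n_oob)`; the regression SE is the standard
error of the mean squared OOB residual. By construction RFE always
returns at least one variable, so it cannot have a zero false-positive
*rate* guarantee on pure noise (documented deviation from the other
selectors' type-I behaviour).

## 5. Stability selection (`forestpower.stability`)

Samples are partitioned into four outer test folds (each sample held
out exactly once; a 75:25 train:test ratio per rotation). Within each
outer training set, one tenth tunes hyperparameters and the remaining
nine tenths host `n_iterations = 100` freshly seeded runs of each
method. The published description names the tuning tenth "inner train"
and the selection nine-tenths "inner test"; the fractions are
configurable. Iterations differ only in random seed by default;
per-iteration subsampling is available but off, and the 100 repetitions
are mapped to the selection iterations rather than to outer restarts
(both knobs exist).

Stability thresholds: **LS** (low stringency) = selected in strictly
more than `ls_threshold = 5` of 100 iterations; **HS** = at least
`hs_threshold = 90`. HS ⊆ LS always, and raising a threshold can only
shrink a set. Frequencies are averaged over the four rotations for the
report-level sets; validation forests are trained per rotation on the
outer-train samples restricted to that rotation's stable set and scored
on the held-out fold (R² for regression, class error for
classification). An empty stable set skips validation with a flag
rather than raising. With known truth, TP counts selections among the
outcome-generating variables (V1-V30 in the benchmark) and FP counts
the rest.

## 6. Power analysis (`forestpower.power`)

**Synthesis.** The feature matrix is modelled as multivariate
log-normal: a per-variable shift (`0` if the variable is already
strictly positive, else `-min + range/100`) makes values positive, and
the mean vector and covariance are estimated on the log scale (the
covariance is symmetrised and eigenvalue-clipped to PSD if needed,
flagged). Synthesis draws log-scale Gaussians and back-transforms.
When the input is genuinely log-normal this round trip preserves the
Pearson correlation matrix (tests check entrywise ±0.02 at n=100000);
strongly non-log-normal positive inputs (e.g. uniform marginals near
zero) can distort exp-scale correlations — a model-assumption
limitation, not an estimation error. Power results are only weakly
sensitive to this because the outcome is constructed directly from the
target variable's standardized column.

**Effect sizes.** Pearson correlation with a continuous outcome;
Cohen's d (|mean difference| / pooled sd) for two groups. Verbal
labels (small .. huge) are annotations only.

**Grouping.** Single-linkage grouping on |Pearson r| >= 0.8 ("highly
correlated" is not quantified in the source methodology; 0.8 is the
package default, configurable). Each group is represented by its
largest-|effect| member, ties to the first in column order.

**Regression power.** Per replicate and sample size `n`: synthesize `n`
samples, build `y = r z + sqrt(1-r^2) eps` with `z` the in-sample
standardized target column and `eps` i.i.d. standard normal, regress
`y` on every variable and collect two-sided slope p-values (equivalent
to the Pearson correlation test). A replicate is a success when the
significant set at `alpha = 0.05` intersects {target} ∪ partners;
power is the success fraction, with the per-variable TPR and the FPR
over non-partner variables reported alongside the binomial Monte-Carlo
standard error. Because `z` is standardized in-sample, the exact
reference is the noncentral-t power of a fixed-design slope test with
`ncp = r sqrt(n) / sqrt(1-r^2)`; the Fisher-z correlation-test power is
a close approximation. Both are used as test oracles.

**Classification power.** Two groups of `n` are synthesized; the target
and its partners in group two are shifted by `d` times the pooled
pre-shift sample standard deviation (so the realized Cohen's d tracks
the request); a one-way ANOVA per variable (two groups, so equivalent
to the t test) yields p-values, and success/TPR/FPR are scored as in
regression.

Defaults: Monte-Carlo `reps = 200` per (variable, n) with the MC
standard error reported (500 in the acceptance runs); sample-size grid
5, 10, 20, ..., 2560 (a doubling series; the source methodology's grid
is illustrative only); `sample_size_recommendation` returns the
smallest grid n reaching the target power or the explicit flag
"beyond grid". Group-aware power is the default ("the biomarker or any
of its correlated partners is detected"); passing an empty partner set
gives the strict per-variable variant.

## 7. Acceptance-run problem sizes

`scripts/acceptance.py` recomputes the headline results at documented
desk-scale conditions: the Boruta stability count runs 100 repeats on a
200 x 1000 uniform simulation, each repeat on a fresh 135-sample
selection subset — the sample size the nested procedure's selection
iterations actually see (nine tenths of a 75% training split) — with
`n_trees = 120` and `mtry = sqrt(p)` (no per-repeat tuning). The power
anchors use 500 Monte-Carlo replicates on a model fitted to the sixty
correlated variables plus one noise variable of the full 5000-predictor
simulation. The normal-variant OOB metrics average five simulation
seeds with 500-tree forests on the fixed stable sets (V1-V10 and
V21-V30 for classification, V1-V10 for regression).

## 8. Known limitations

* The normal-latent variant of the benchmark produces a heavy-tailed
  outcome (the `exp(4 x_1)` term), so OOB %variance explained is
  dominated by the largest draws and varies strongly across seeds; its
  median-split classes hinge on the unobserved sigmoid term near the
  boundary. The package reports the honest OOB values.
* Exact stable-set counts for the weaker selectors (permutation, RFE at
  the stringency margin) depend on the predictor count and the
  permutation budget; desk-scale runs reproduce the stable Boruta
  counts exactly but not every full-scale count (see the acceptance
  suite's per-check documentation).
* Selection frequency is interpreted per-iteration-seed; alternative
  readings (outer restarts, per-iteration subsampling) are exposed as
  flags but not the default.
* Missing feature values are a hard error; no imputation is attempted.
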