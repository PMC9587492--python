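# Methods

## Problem setting

Frailty in older adults is commonly quantified by a deficit-accumulation
frailty index (FI): the proportion of a panel of binary health deficits a
person exhibits.  An electronic FI (eFI) computed from care records is
attractive for screening, but many of the deficit items are expensive to
obtain — they require chart review of unstructured notes and clinician
verification — while routinely collected administrative assessment items are
essentially free.  `pgaselect` implements a cost-aware wrapper
feature-selection method for this setting: a **partial genetic algorithm**
that forces a fixed set of low-cost features into every candidate model and
evolves only a capped subset of the high-cost features, exposing the
trade-off between the number of expensive features acquired and screening
performance.

## The eFI outcome

For a record with deficit vector `d ∈ {0,1,NA}^p`,

    fi = (# deficits present) / (# deficits assessed),   frail ⇔ fi > τ

with threshold `τ = 0.21` and a *strict* inequality (a record exactly at the
threshold is non-frail).  Missing deficits reduce the denominator, the
standard convention for accumulation-of-deficits indices.  A record with
fewer than `min_assessed_fraction` (default 0.8) of the panel assessed is
flagged uncomputable and excluded from labelling rather than scored.
Deficits are strictly binary; graded deficit scoring is out of scope.

## The partial genetic algorithm

A chromosome `c` is a bit vector over the selectable (high-cost) features.
Fitness of `c` is the mean stratified k-fold cross-validated score (default
k = 3, metric = accuracy) of the chosen classifier trained on the columns
`fixed ∪ selected(c)`; the low-cost fixed set is injected into every fold's
design matrix, training and evaluation alike.  Folds are generated once per
run from the run seed and shared across all chromosomes so fitnesses are
directly comparable; fitness values are cached by chromosome bits.

One generation is: evaluate → truncation selection (remove the worst
fraction `q`, default 0.5) → copy the top `e = 2` chromosomes unchanged
(elitism) → refill the population by uniform crossover (per-bit swap
probability 0.5) between parent pairs drawn uniformly from the survivors →
per-bit mutation (default rate `2/n`) → **cap repair**.  Repair enforces the
budget constraint exactly: if `popcount(c) > m` random excess bits are
cleared; an all-zero chromosome gets one random bit.  The engine asserts
`1 ≤ popcount ≤ m` for every chromosome it evaluates.  The run stops after
`max_generations` or when the best fitness has improved by less than
`plateau_epsilon = 1e-4` for `plateau_patience = 10` consecutive
generations.  The best chromosome (ties broken toward fewer selected
high-cost features, then lexicographically — deterministic and aligned with
the cost-minimisation goal) is refit on the full training data and, when a
test table is supplied, scored on it.

Design choices where the procedure was genuinely open: truncation selection
with uniform parent sampling (rather than tournament or roulette) because
the method is described as removing the worst performers outright and
breeding the best; uniform crossover; cap enforcement by random repair
rather than a fitness penalty, so every cap in a sweep is honoured exactly;
population 50 and 100 generations as defaults, standard GA practice.  The
optimised fitness metric is configurable to any of the six reported metrics.

A **standard GA** is the same engine with an empty fixed set and
`cap = |candidates|`; the **two-stage** procedure first runs the standard GA
over the low-cost features and then uses its selection as the fixed set of a
partial-GA run.

## Classifier adapters

Four families behind one train/predict contract: logistic regression (L2,
`max_iter=2000`), RBF-kernel SVM, decision tree (entropy criterion), and
random forest (100 trees).  Logistic regression and the SVM are wrapped in a
standardisation pipeline whose scaling parameters are learned on the
training folds only; tree models consume raw codes.  All randomness is tied
to the spec seed, so identical spec + data give identical predictions.
Prediction refuses matrices whose column set or order differs from the one
used at fit time.  Hyperparameter search is out of scope — the GA optimises
feature subsets, not hyperparameters.

## Metrics

From the confusion matrix: sensitivity `tp/(tp+fn)`, specificity
`tn/(tn+fp)`, positive/negative percent agreement implemented as
predictive-value-style agreement `ppa = tp/(tp+fp)`, `npa = tn/(tn+fn)`,
accuracy, and F1 = harmonic mean of PPA and sensitivity, all on the
percentage scale.  The positive class is an explicit parameter: swapping it
exchanges (sensitivity, specificity) and (PPA, NPA), so either class
convention for the agreement columns can be reproduced.  A metric with an
empty denominator is reported as NaN, never as 0.

## Scenario grid

The study design crosses four fixed low-cost sets — all low-cost features;
only the derived low-cost deficits; none (to measure what the low-cost
features add); a set chosen by the standard GA, recomputed per classifier —
with the four classifier families (16 scenarios) and sweeps the cap over
1..32.  Per-cell seeds are derived by hashing (master seed, mode,
classifier, cap), so extending a sweep never perturbs existing cells, and a
failed cell is recorded rather than dropped.  Reports render one comparison
table per requested cap and one metric-vs-cap curve per scenario.

## Synthetic cohort generator

The generator emulates the structure the method assumes, not any real
cohort.  A latent frailty trait `z ~ N(0,1)` per record drives:

- **32 stochastic high-cost deficits** `d_j ~ Bernoulli(σ(a_j z + b_j))`,
  conditionally independent given `z`; default loadings ramp over
  [0.8, 1.8] and intercepts over [−1.6, −0.4].
- **32 clean ordinal administrative features** (3–5 levels), discretised
  from `s·z + √(1−s²)·ε` with signal strength `s = 0.55` — strong enough
  that low-cost features add predictive value, weak enough that they are
  insufficient on their own.
- **2 additional administrative scales** with 36% and 42% MCAR missingness,
  so the missingness filter (default threshold 0.30, separating the
  observed 0% from 36%/42%) exercises its exclusion path on defaults.
- **3 derived low-cost deficits**: deterministic binary combinations of
  administrative features expressed in the safe expression mini-grammar and
  recorded in the schema, so they are fully automatable from administrative
  data.  They complete the 35-item eFI panel.  (The real combination rules
  are not public; the grammar-based rules stand in, and loadings/intercepts
  therefore apply only to the 32 stochastic deficits.)

The label is the eFI over the panel thresholded strictly at 0.21 and is
computed before missingness is applied, so `label_table` on the clean table
reproduces the generated labels exactly.  With a target prevalence set
(default 0.55, matching the positive-heavy class balance the reported test
counts imply), a common intercept shift is found by bisection on the
realised data within ±6 logits until the observed prevalence is within
0.02; an unreachable target raises after the bounded search.

**Planted-subset cohorts** give ground truth for recovery benchmarks:
exactly `n_informative` deficits receive loading +2 and the rest loading 0
(pure Bernoulli noise, prevalence ≈ 0.3).  The eFI panel of these cohorts is
the informative set itself, so noise deficits are label-independent by
construction and a selector's output can be scored against the planted set.

What the generator does **not** emulate: inter-deficit dependence beyond the
single factor, informative (non-MCAR) missingness, measurement error in the
deficit extraction, and the covariance structure of any real administrative
instrument.  Passing tests therefore demonstrate correctness and the
qualitative cost/accuracy behaviour of the machinery, not clinical
performance on real data.

## Data handling defaults

Test split 0.25, stratified (a study-level choice; the original split is
not public).  Record-level missing values in retained features are imputed
with the training-split mode (categorical codes) or median (continuous),
because the classifier adapters require complete matrices.  Ordinal
features are integer codes; the schema's value domains are binary,
ordinal(k) and continuous, so no one-hot encoding is needed.

## Problem sizes used by the test suite

The heavier end-to-end properties run at sizes chosen to keep the whole
suite comfortably interactive while preserving the studied structure:
GA-vs-exhaustive-enumeration uses 20 cohorts of 300 records with 10
candidate deficits at cap 3 (population 40, 60 generations); subset
recovery uses 20 cohorts of 600 records with 5 informative of 32 deficits at
cap 5; the qualitative cost/accuracy checks use 10 replicates of the
592-record reference cohort with population 20 / 15 generations; and the
full 512-cell scenario sweep uses a 200-record cohort at population 12 / 10
generations with an 8-tree forest.  The plateau rule usually terminates runs
well before the generation limit.

## Known limitations

- The GA is single-objective; cost enters only through the fixed set and
  the cap, not as a second objective (no Pareto front).
- Exhaustive-oracle agreement is only verified for small search spaces;
  for 32 candidates the optimum is unknowable and only qualitative
  dominance properties are checked.
- Graded deficits, frailty-phenotype outcomes and free-text deficit
  extraction are out of scope.
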