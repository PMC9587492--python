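# pgaselect

Cost-aware feature selection for frailty screening with **partial genetic
algorithms**.

## The problem

Deficit-accumulation frailty indices (FI) classify an older person as frail
when the proportion of health deficits present exceeds a threshold — here an
electronic FI (eFI) over a 35-item panel with the rule `frail ⇔ fi > 0.21`.
In aged-care databases most deficit items are *expensive*: they must be
extracted from unstructured patient notes and verified by a clinician.
Administrative assessment items, by contrast, are routinely collected and
essentially free.  A useful screening test should therefore lean on the
cheap features and acquire as few expensive ones as possible.

A standard genetic algorithm (GA) wrapper selects the feature subset that
maximises cross-validated classifier performance — but it is cost-blind and
tends to pick expensive features.  The **partial GA** modifies the wrapper:
a fixed set of low-cost features is injected into *every* model trained
during the search, while the GA evolves only a bit vector `c` over the
high-cost features under a hard cap `popcount(c) ≤ m`.  The fitness of a
chromosome is its mean stratified 3-fold cross-validated score:

    fitness(c) = (1/k) Σ_f  score( clf fitted on (fixed ∪ selected(c)), fold f )

Sweeping `m` from 1 to 32 across four low-cost-set scenarios (all low-cost
features / only the derived low-cost eFI items / none / a GA-chosen set) and
four classifier families (logistic regression, SVM, decision tree, random
forest) maps the cost/accuracy trade-off and identifies screening models
that are accurate with only a handful of expensive features.

The package ships the full pipeline: schema-driven table I/O and cost
partitioning, the eFI labeller, the four classifier adapters, the six
screening metrics (sensitivity, specificity, PPA, NPA, accuracy, F1), the
partial/standard/two-stage GA engines, the 16-scenario cap-sweep runner
with tables and curves, and a synthetic cohort generator with a latent
frailty trait so everything is testable without private data.

## Worked example

```python
import pgaselect as pg

# a 592-record synthetic cohort: 34 administrative features (2 with heavy
# missingness), 3 derived low-cost deficits, 32 high-cost deficits
cohort = pg.generate(pg.SyntheticConfig(seed=1))
table, dropped = pg.missingness_filter(cohort.table)   # drops adm_33, adm_34
train, test = pg.split_train_test(table, seed=1)
partition = cohort.schema.partition(table.feature_names)
print(len(partition.low_cost), len(partition.high_cost))   # 35 32

# partial GA: all low-cost features fixed, at most 10 high-cost deficits
result = pg.run_pga(
    train, partition,
    fixed=partition.low_cost,
    spec=pg.ClassifierSpec("logistic_regression", seed=1),
    config=pg.GAConfig(population_size=30, max_generations=30, cap=10, seed=1),
    test_table=test,
)
print(len(result.selected_high_cost))          # 10
print(result.test_metrics.rounded())
# {'sensitivity': 87.8, 'specificity': 83.3, 'ppa': 86.7, 'npa': 84.6,
#  'accuracy': 85.8, 'f1': 87.3}
```

The model reaches ~88%/83% sensitivity/specificity while acquiring only 10
of the 32 expensive deficit items — the low-cost administrative block plus a
small, GA-chosen expensive subset.  (On this synthetic cohort the label is
by construction a linear threshold of the full deficit panel, so a model
given all 32+3 deficits is near-perfect; the interesting question is how
little of that panel a capped model needs.)

The same pipeline is available from the shell:

```sh
pgaselect simulate --out-dir cohort --n-records 592 --seed 1
pgaselect select   --table cohort/cohort.csv --schema cohort/schema.yaml \
                   --classifier logistic_regression --mode all_low_cost \
                   --cap 10 --seed 1 --out-dir run
pgaselect sweep    --table cohort/cohort.csv --schema cohort/schema.yaml \
                   --caps 1:32 --seed 1 --out-dir sweep
pgaselect report   --results sweep/results.csv --caps 5,10,15 --out-dir report
```

`sweep` writes a long-format results CSV (one row per scenario × cap);
`report` renders per-cap comparison tables and metric-vs-cap curves.

## Layout

| module | contents |
| --- | --- |
| `pgaselect.data` | `FeatureTable`, `FeatureSchema`, CSV/YAML I/O, missingness filter, derived features, splitting, imputation |
| `pgaselect.efi` | eFI configuration, per-record and vectorised index, table labelling |
| `pgaselect.classifiers` | the four classifier families behind one train/predict contract |
| `pgaselect.metrics` | confusion matrix and the six screening metrics |
| `pgaselect.ga` | chromosome operators, the `PartialGeneticSelector` estimator, `run_pga` / `run_standard_ga` / `run_two_stage` |
| `pgaselect.scenarios` | the 16-scenario cap-sweep grid, reports and curves |
| `pgaselect.synth` | latent-trait synthetic cohort generator and planted-subset fixtures |
| `pgaselect.cli` | `pgaselect` command-line interface |

`PartialGeneticSelector` follows the scikit-learn estimator protocol
(`fit`/`transform`/`predict`, `get_params`, clone-safe), so it composes with
sklearn pipelines and model selection.

See `docs/methods.md` for the model, the generator's assumptions, numerical
choices and known limitations.
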