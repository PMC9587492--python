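"""Partial genetic algorithm: capped subset search over high-cost features
with a fixed low-cost feature set injected into every model evaluation.

A chromosome is a bit vector over the selectable (high-cost) features.  Every
fitness evaluation trains the classifier on ``fixed ∪ selected`` columns
under stratified k-fold cross-validation; the folds are generated once per
run so that fitnesses are comparable across chromosomes.  The population
evolves by truncation selection (worst fraction removed), elitism, uniform
crossover and per-bit mutation, with a repair step that enforces
``1 ≤ popcount ≤ cap`` after every variation.  Fitness ties are broken in
favour of fewer selected high-cost features (cost-aware), then
lexicographically smaller bit vectors, so results are deterministic.

The engine is exposed both as the scikit-learn style estimator
:class:`PartialGeneticSelector` and as table-level runners
(:func:`run_pga`, :func:`run_standard_ga`, :func:`run_two_stage`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, FittedModel, train
from .data import CostPartition, FeatureTable, apply_imputer, fit_imputer
from .metrics import MetricsReport, fraction_score, score_predictions

Chromosome = np.ndarray  # dtype uint8, one bit per selectable feature


class ConstraintViolationError(RuntimeError):
    """A chromosome outside 1 ≤ popcount ≤ cap reached evaluation."""


class PopulationCollapseError(RuntimeError):
    """Fewer than two chromosomes survived truncation."""


@dataclass(frozen=True)
class GAConfig:
    """Evolution-loop parameters.

    ``cap`` is the maximum number of high-cost features a chromosome may
    select (``None`` = all selectable).  ``mutation_rate=None`` defaults to
    ``2 / n_selectable`` at run time.  Termination: ``max_generations``
    reached, or best fitness improved by less than ``plateau_epsilon`` for
    ``plateau_patience`` consecutive generations.
    """

    population_size: int = 50
    max_generations: int = 100
    crossover_rate: float = 0.5
    mutation_rate: float | None = None
    elitism: int = 2
    truncation_fraction: float = 0.5
    cv_folds: int = 3
    cap: int | None = None
    plateau_patience: int = 10
    plateau_epsilon: float = 1e-4
    fitness_metric: str = "accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        for name in ("crossover_rate", "truncation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        survivors = self.population_size * (1.0 - self.truncation_fraction)
        if self.elitism >= max(survivors, 1):
            raise ValueError("elitism must be smaller than the surviving population")


@dataclass(frozen=True)
class FitnessRecord:
    """Cross-validated fitness of one chromosome."""

    chromosome: bytes
    mean_cv_score: float
    per_fold_scores: tuple[float, ...]


@dataclass
class PGAResult:
    """Outcome of one partial-GA run."""

    best_chromosome: np.ndarray
    selected_high_cost: tuple[str, ...]
    fixed_low_cost: tuple[str, ...]
    history: pd.DataFrame  # generation, best, mean, best_popcount
    best_cv_score: float
    final_model: FittedModel
    test_metrics: MetricsReport | None = None
    n_evaluations: int = 0
    constraint_checks: int = 0
    stage1_selected: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# chromosome operators


def popcount(chrom: Chromosome) -> int:
    return int(np.sum(chrom))


def _rng_for(config: GAConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def init_population(
    n_selectable: int, config: GAConfig, rng: np.random.Generator | None = None
) -> list[Chromosome]:
    """P random chromosomes with popcount uniform on [1, cap]."""
    if n_selectable < 1:
        raise ValueError("need at least one selectable feature")
    cap = config.cap if config.cap is not None else n_selectable
    if not 1 <= cap <= n_selectable:
        raise ValueError(f"cap must lie in [1, {n_selectable}], got {cap}")
    rng = _rng_for(config, rng)
    population = []
    for _ in range(config.population_size):
        k = int(rng.integers(1, cap + 1))
        chrom = np.zeros(n_selectable, dtype=np.uint8)
        chrom[rng.choice(n_selectable, size=k, replace=False)] = 1
        population.append(chrom)
    return population


def repair_cap(chrom: Chromosome, cap: int, rng: np.random.Generator) -> Chromosome:
    """Clear random excess bits above the cap; set one bit if all are zero."""
    chrom = chrom.copy()
    count = popcount(chrom)
    if count > cap:
        set_bits = np.flatnonzero(chrom)
        drop = rng.choice(set_bits, size=count - cap, replace=False)
        chrom[drop] = 0
    elif count == 0:
        chrom[int(rng.integers(len(chrom)))] = 1
    return chrom


def crossover(
    p1: Chromosome, p2: Chromosome, config: GAConfig, rng: np.random.Generator | None = None
) -> tuple[Chromosome, Chromosome]:
    """Uniform crossover: each bit swapped with probability ``crossover_rate``."""
    if len(p1) != len(p2):
        raise ValueError("parents have different lengths")
    rng = _rng_for(config, rng)
    swap = rng.random(len(p1)) < config.crossover_rate
    c1, c2 = p1.copy(), p2.copy()
    c1[swap], c2[swap] = p2[swap], p1[swap]
    return c1, c2


def mutate(chrom: Chromosome, config: GAConfig, rng: np.random.Generator | None = None) -> Chromosome:
    """Per-bit flips at the mutation rate, followed by cap repair."""
    rng = _rng_for(config, rng)
    rate = config.mutation_rate if config.mutation_rate is not None else 2.0 / len(chrom)
    flips = rng.random(len(chrom)) < rate
    mutated = np.where(flips, 1 - chrom, chrom).astype(np.uint8)
    cap = config.cap if config.cap is not None else len(chrom)
    return repair_cap(mutated, cap, rng)


def fitness_key(score: float, chrom: Chromosome) -> tuple:
    """Ascending sort key: higher score first, then fewer bits, then lexicographic."""
    return (-score, popcount(chrom), tuple(int(b) for b in chrom))


def select_survivors_and_parents(
    population: Sequence[Chromosome],
    fitnesses: Sequence[float],
    config: GAConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Chromosome], list[tuple[Chromosome, Chromosome]]]:
    """Truncation selection: drop the worst ⌈q·P⌉, pair parents uniformly.

    Returns the survivors (best first) and enough uniformly drawn parent
    pairs to refill the population to P alongside the elite copies.
    """
    rng = _rng_for(config, rng)
    P = len(population)
    order = sorted(range(P), key=lambda i: fitness_key(fitnesses[i], population[i]))
    n_remove = math.ceil(config.truncation_fraction * P)
    survivors = [population[i] for i in order[: P - n_remove]]
    if len(survivors) < 2:
        raise PopulationCollapseError(
            f"population collapse: only {len(survivors)} survivor(s) after truncation"
        )
    n_children = config.population_size - config.elitism
    pairs = []
    for _ in range(math.ceil(n_children / 2)):
        i, j = rng.choice(len(survivors), size=2, replace=False)
        pairs.append((survivors[int(i)], survivors[int(j)]))
    return survivors, pairs


# ---------------------------------------------------------------------------
# fitness evaluation


def make_cv_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs, fixed by ``seed``.

    Generated once per GA run and shared by every chromosome so that mean CV
    fitnesses are directly comparable.
    """
    y = np.asarray(y, dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31 - 1))
    return [(tr, te) for tr, te in splitter.split(np.zeros((len(y), 1)), y)]


def augment_with_fixed(
    frame: pd.DataFrame, selected: Sequence[str], fixed: Sequence[str]
) -> pd.DataFrame:
    """Design matrix with exactly the columns ``fixed + selected``, in that order."""
    overlap = set(fixed) & set(selected)
    if overlap:
        raise ValueError(f"features in both fixed and selected sets: {sorted(overlap)}")
    return frame[list(fixed) + list(selected)]


def evaluate_subset_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_names: Sequence[str],
    spec: ClassifierSpec,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    metric: str = "accuracy",
) -> tuple[float, ...]:
    """Per-fold scores of *spec* trained on ``X[feature_names]``.

    A fold whose training part is single-class (untrainable) scores 0 with
    a warning instead of raising.
    """
    matrix = X[list(feature_names)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    scores = []
    for train_idx, test_idx in folds:
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            warnings.warn("single-class training fold; assigning worst score", stacklevel=2)
            scores.append(0.0)
            continue
        estimator = spec.build()
        estimator.fit(matrix[train_idx], y_tr)
        pred = np.asarray(estimator.predict(matrix[test_idx]), dtype=int)
        scores.append(fraction_score(y[test_idx], pred, metric))
    return tuple(scores)


def evaluate_chromosome(
    chrom: Chromosome,
    train_table: FeatureTable,
    fixed: Sequence[str],
    spec: ClassifierSpec,
    config: GAConfig,
    selectable: Sequence[str] | None = None,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> FitnessRecord:
    """Stand-alone fitness of one chromosome over a labelled table.

    ``selectable`` defaults to every non-fixed column, in table order; folds
    default to the shared per-run folds derived from ``config.seed``.
    """
    if train_table.label is None:
        raise ValueError("training table has no label")
    if selectable is None:
        selectable = [n for n in train_table.feature_names if n not in set(fixed)]
    names = [s for s, bit in zip(selectable, chrom) if bit]
    design = augment_with_fixed(train_table.values, names, fixed)
    y = train_table.label.to_numpy()
    if folds is None:
        folds = make_cv_folds(y, config.cv_folds, config.seed)
    scores = evaluate_subset_cv(design, y, list(design.columns), spec, folds, config.fitness_metric)
    return FitnessRecord(
        chromosome=np.asarray(chrom, dtype=np.uint8).tobytes(),
        mean_cv_score=float(np.mean(scores)),
        per_fold_scores=scores,
    )


# ---------------------------------------------------------------------------
# estimator


class PartialGeneticSelector(BaseEstimator):
    """Cost-aware wrapper feature selection with a partial genetic algorithm.

    Fits a classifier on ``fixed_features ∪ (an evolved subset of
    selectable_features)`` where the evolved subset contains at most ``cap``
    features.  Follows the scikit-learn estimator protocol: ``fit`` consumes
    a DataFrame (column names identify features) and a binary target;
    ``transform`` reduces a frame to the chosen columns; ``predict``
    delegates to the final model refit on the full training data.

    Parameters
    ----------
    classifier:
        A :class:`~pgaselect.classifiers.ClassifierSpec` or one of
        ``{"logistic_regression", "svm", "decision_tree", "random_forest"}``.
    fixed_features:
        Low-cost columns forced into every evaluated model.
    selectable_features:
        Candidate (high-cost) columns the GA may select; default: every
        column of ``X`` not in ``fixed_features``.
    cap:
        Maximum number of selectable features per chromosome (None = all).
    fitness_metric:
        MetricsReport field maximised by the search (default ``accuracy``).
    random_state:
        Seed for population initialisation, variation, and the shared CV
        folds; identical inputs and seed give bit-identical histories.

    Attributes
    ----------
    selected_features_ : tuple of str
        The evolved high-cost subset.
    best_score_ : float
        Mean CV fitness of the best chromosome (0–1 scale).
    history_ : DataFrame
        Per-generation ``best``/``mean`` fitness and best popcount.
    model_ : FittedModel
        Final classifier refit on all training records.
    """

    def __init__(
        self,
        classifier="logistic_regression",
        fixed_features: Sequence[str] = (),
        selectable_features: Sequence[str] | None = None,
        cap: int | None = None,
        population_size: int = 50,
        max_generations: int = 100,
        crossover_rate: float = 0.5,
        mutation_rate: float | None = None,
        elitism: int = 2,
        truncation_fraction: float = 0.5,
        cv_folds: int = 3,
        plateau_patience: int = 10,
        plateau_epsilon: float = 1e-4,
        fitness_metric: str = "accuracy",
        random_state: int = 0,
    ):
        self.classifier = classifier
        self.fixed_features = fixed_features
        self.selectable_features = selectable_features
        self.cap = cap
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.truncation_fraction = truncation_fraction
        self.cv_folds = cv_folds
        self.plateau_patience = plateau_patience
        self.plateau_epsilon = plateau_epsilon
        self.fitness_metric = fitness_metric
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _spec(self) -> ClassifierSpec:
        if isinstance(self.classifier, ClassifierSpec):
            return self.classifier
        return ClassifierSpec(kind=self.classifier, seed=self.random_state)

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism=self.elitism,
            truncation_fraction=self.truncation_fraction,
            cv_folds=self.cv_folds,
            cap=self.cap,
            plateau_patience=self.plateau_patience,
            plateau_epsilon=self.plateau_epsilon,
            fitness_metric=self.fitness_metric,
            seed=self.random_state,
        )

    # -- estimator protocol -------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "PartialGeneticSelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=int)
        config = self._config()
        spec = self._spec()
        fixed = tuple(self.fixed_features)
        if self.selectable_features is not None:
            selectable = tuple(self.selectable_features)
        else:
            selectable = tuple(n for n in X.columns if n not in set(fixed))
        if not selectable:
            raise ValueError("no selectable (high-cost) features to search over")
        missing = [n for n in (*fixed, *selectable) if n not in X.columns]
        if missing:
            raise ValueError(f"feature(s) absent from X: {missing}")
        n = len(selectable)
        cap = config.cap if config.cap is not None else n
        if not 1 <= cap <= n:
            raise ValueError(f"cap must lie in [1, {n}], got {cap}")
        if np.isnan(X[list(fixed) + list(selectable)].to_numpy(dtype=float)).any():
            raise ValueError("X contains missing values; impute before fitting")

        rng = np.random.default_rng(config.seed)
        folds = make_cv_folds(y, config.cv_folds, config.seed)
        design = augment_with_fixed(X, list(selectable), list(fixed))
        cache: dict[bytes, FitnessRecord] = {}
        checks = 0

        def evaluate(chrom: Chromosome) -> FitnessRecord:
            nonlocal checks
            pc = popcount(chrom)
            checks += 1
            if not 1 <= pc <= cap:
                raise ConstraintViolationError(
                    f"chromosome popcount {pc} outside [1, {cap}] reached evaluation"
                )
            key = chrom.tobytes()
            record = cache.get(key)
            if record is None:
                names = list(fixed) + [s for s, bit in zip(selectable, chrom) if bit]
                scores = evaluate_subset_cv(design, y, names, spec, folds, config.fitness_metric)
                record = FitnessRecord(key, float(np.mean(scores)), scores)
                cache[key] = record
            return record

        population = init_population(n, config, rng)
        records = [evaluate(c) for c in population]
        history_rows = []
        best_chrom: Chromosome | None = None
        best_score = -np.inf
        plateau = 0

        def log_generation(gen: int) -> None:
            nonlocal best_chrom, best_score, plateau
            idx = min(
                range(len(population)),
                key=lambda i: fitness_key(records[i].mean_cv_score, population[i]),
            )
            gen_best = records[idx].mean_cv_score
            improvement = gen_best - best_score
            if best_chrom is None or fitness_key(gen_best, population[idx]) < fitness_key(
                best_score, best_chrom
            ):
                best_chrom = population[idx].copy()
                best_score = gen_best
            plateau = plateau + 1 if improvement < config.plateau_epsilon else 0
            history_rows.append(
                {
                    "generation": gen,
                    "best": gen_best,
                    "mean": float(np.mean([r.mean_cv_score for r in records])),
                    "best_popcount": popcount(population[idx]),
                }
            )

        log_generation(0)
        for gen in range(1, config.max_generations + 1):
            if plateau >= config.plateau_patience:
                break
            scores = [r.mean_cv_score for r in records]
            order = sorted(
                range(len(population)), key=lambda i: fitness_key(scores[i], population[i])
            )
            elite = [population[i].copy() for i in order[: config.elitism]]
            _, pairs = select_survivors_and_parents(population, scores, config, rng)
            children: list[Chromosome] = []
            for p1, p2 in pairs:
                for child in crossover(p1, p2, config, rng):
                    children.append(mutate(child, config, rng))
            population = elite + children[: config.population_size - config.elitism]
            records = [evaluate(c) for c in population]
            log_generation(gen)

        assert best_chrom is not None
        selected = tuple(s for s, bit in zip(selectable, best_chrom) if bit)
        self.best_chromosome_ = best_chrom
        self.selected_features_ = selected
        self.fixed_features_ = fixed
        self.selectable_features_ = selectable
        self.best_score_ = float(best_score)
        self.history_ = pd.DataFrame(history_rows)
        self.cv_folds_ = folds
        self.n_evaluations_ = len(cache)
        self.constraint_checks_ = checks
        self.model_ = train(spec, augment_with_fixed(X, list(selected), list(fixed)), y)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        return augment_with_fixed(X, list(self.selected_features_), list(self.fixed_features_))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict(self.transform(X))

    def get_support(self) -> np.ndarray:
        self._check_fitted()
        return self.best_chromosome_.astype(bool)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("selector is not fitted; call fit first")


# ---------------------------------------------------------------------------
# table-level runners


def _prepare(
    train_table: FeatureTable, test_table: FeatureTable | None, features: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame | None, np.ndarray | None]:
    if train_table.label is None:
        raise ValueError("training table has no label")
    sub = train_table.select_features(features)
    fills = fit_imputer(sub)
    Xtr = apply_imputer(sub, fills).values
    ytr = train_table.label.to_numpy()
    Xte = yte = None
    if test_table is not None:
        if test_table.label is None:
            raise ValueError("test table has no label")
        Xte = apply_imputer(test_table.select_features(features), fills).values
        yte = test_table.label.to_numpy()
    return Xtr, ytr, Xte, yte


def run_pga(
    train_table: FeatureTable,
    partition: CostPartition,
    fixed: Sequence[str],
    spec: ClassifierSpec,
    config: GAConfig,
    test_table: FeatureTable | None = None,
) -> PGAResult:
    """One partial-GA run over a labelled table.

    ``fixed`` must be a subset of the partition's low-cost features; the
    search space is the partition's high-cost features.  Residual missing
    cells are imputed from the training split (mode/median of codes).  When
    a test table is supplied, the final refit model is scored on it.
    """
    if not partition.high_cost:
        raise ValueError("cost partition has no high-cost features to search over")
    bad = set(fixed) - set(partition.low_cost)
    if bad:
        raise ValueError(f"fixed feature(s) not in the low-cost set: {sorted(bad)}")
    features = list(fixed) + list(partition.high_cost)
    Xtr, ytr, Xte, yte = _prepare(train_table, test_table, features)
    selector = PartialGeneticSelector(
        classifier=spec,
        fixed_features=tuple(fixed),
        selectable_features=partition.high_cost,
        cap=config.cap,
        population_size=config.population_size,
        max_generations=config.max_generations,
        crossover_rate=config.crossover_rate,
        mutation_rate=config.mutation_rate,
        elitism=config.elitism,
        truncation_fraction=config.truncation_fraction,
        cv_folds=config.cv_folds,
        plateau_patience=config.plateau_patience,
        plateau_epsilon=config.plateau_epsilon,
        fitness_metric=config.fitness_metric,
        random_state=config.seed,
    )
    selector.fit(Xtr, ytr)
    test_metrics = None
    if Xte is not None:
        pred = selector.predict(Xte)
        test_metrics = score_predictions(yte, pred)
    return PGAResult(
        best_chromosome=selector.best_chromosome_,
        selected_high_cost=selector.selected_features_,
        fixed_low_cost=selector.fixed_features_,
        history=selector.history_,
        best_cv_score=selector.best_score_,
        final_model=selector.model_,
        test_metrics=test_metrics,
        n_evaluations=selector.n_evaluations_,
        constraint_checks=selector.constraint_checks_,
    )


def run_standard_ga(
    train_table: FeatureTable,
    candidate_features: Sequence[str],
    spec: ClassifierSpec,
    config: GAConfig,
) -> tuple[str, ...]:
    """Standard (non-partial) GA: unconstrained subset search.

    The same engine with an empty fixed set and cap = all candidates;
    returns the selected feature names.
    """
    candidates = tuple(candidate_features)
    if not candidates:
        raise ValueError("candidate_features must be non-empty")
    Xtr, ytr, _, _ = _prepare(train_table, None, list(candidates))
    selector = PartialGeneticSelector(
        classifier=spec,
        fixed_features=(),
        selectable_features=candidates,
        cap=None,
        population_size=config.population_size,
        max_generations=config.max_generations,
        crossover_rate=config.crossover_rate,
        mutation_rate=config.mutation_rate,
        elitism=config.elitism,
        truncation_fraction=config.truncation_fraction,
        cv_folds=config.cv_folds,
        plateau_patience=config.plateau_patience,
        plateau_epsilon=config.plateau_epsilon,
        fitness_metric=config.fitness_metric,
        random_state=config.seed,
    )
    selector.fit(Xtr, ytr)
    return selector.selected_features_


def run_two_stage(
    train_table: FeatureTable,
    partition: CostPartition,
    spec: ClassifierSpec,
    stage1_config: GAConfig,
    stage2_config: GAConfig,
    test_table: FeatureTable | None = None,
) -> PGAResult:
    """Two-stage procedure: standard GA over the low-cost features chooses the
    fixed set, then a partial GA evolves the high-cost subset around it."""
    if not partition.low_cost:
        raise ValueError("two-stage run requires a non-empty low-cost set")
    stage1 = run_standard_ga(train_table, partition.low_cost, spec, stage1_config)
    if not stage1:
        warnings.warn(
            "stage-1 GA selected no low-cost features; proceeding with an empty fixed set",
            stacklevel=2,
        )
    result = run_pga(train_table, partition, stage1, spec, stage2_config, test_table)
    result.stage1_selected = stage1
    return result
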