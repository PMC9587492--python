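import numpy as np
import pandas as pd
import pytest

from pgaselect import (
    ClassifierSpec,
    FeatureTable,
    GAConfig,
    PartialGeneticSelector,
    run_pga,
    run_standard_ga,
    run_two_stage,
)
from pgaselect.ga import (
    augment_with_fixed,
    crossover,
    evaluate_chromosome,
    fitness_key,
    init_population,
    make_cv_folds,
    mutate,
    popcount,
    repair_cap,
    select_survivors_and_parents,
)

LR = ClassifierSpec("logistic_regression", seed=0)


def chrom(bits):
    return np.asarray(bits, dtype=np.uint8)


@pytest.fixture
def leak_table():
    """One deficit equals the label; the others are noise."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 120)
    values = pd.DataFrame(
        {
            "low_1": rng.integers(0, 3, 120).astype(float),
            "leak": y.astype(float),
            "noise_1": rng.integers(0, 2, 120).astype(float),
            "noise_2": rng.integers(0, 2, 120).astype(float),
        }
    )
    return FeatureTable(values=values, label=pd.Series(y, index=values.index))


class TestInitPopulation:
    def test_popcounts_respect_cap(self):
        config = GAConfig(population_size=10, cap=3, seed=1)
        population = init_population(32, config)
        assert len(population) == 10
        assert all(1 <= popcount(c) <= 3 for c in population)

    def test_cap_one_forces_single_bit(self):
        population = init_population(32, GAConfig(population_size=20, cap=1, seed=2))
        assert all(popcount(c) == 1 for c in population)

    def test_seed_determinism(self):
        config = GAConfig(population_size=15, cap=4, seed=3)
        a = init_population(10, config)
        b = init_population(10, config)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_cap_above_n_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            init_population(3, GAConfig(population_size=4, elitism=1, cap=5))


class TestAugment:
    def test_column_order_contract(self):
        frame = pd.DataFrame(np.zeros((2, 3)), columns=["d3", "a1", "a2"])
        out = augment_with_fixed(frame, selected=["d3"], fixed=["a1", "a2"])
        assert list(out.columns) == ["a1", "a2", "d3"]

    def test_empty_fixed_set(self):
        frame = pd.DataFrame(np.zeros((2, 2)), columns=["d1", "d2"])
        out = augment_with_fixed(frame, selected=["d2"], fixed=[])
        assert list(out.columns) == ["d2"]

    def test_overlap_rejected(self):
        frame = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="both fixed and selected"):
            augment_with_fixed(frame, selected=["a"], fixed=["a", "b"])

    def test_commutes_with_fold_splitting(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        idx = np.arange(0, 30, 2)
        first = augment_with_fixed(frame, ["d"], ["a"]).iloc[idx]
        second = augment_with_fixed(frame.iloc[idx], ["d"], ["a"])
        pd.testing.assert_frame_equal(first, second)


class TestVariationOperators:
    def test_crossover_identity_cases(self):
        config = GAConfig(crossover_rate=0.7, seed=0)
        p = chrom([1, 0, 1, 0])
        c1, c2 = crossover(p, p.copy(), config)
        assert np.array_equal(c1, p) and np.array_equal(c2, p)
        c1, c2 = crossover(chrom([1, 0, 0, 1]), chrom([0, 1, 1, 0]),
                           GAConfig(crossover_rate=0.0, seed=0))
        assert np.array_equal(c1, chrom([1, 0, 0, 1]))
        assert np.array_equal(c2, chrom([0, 1, 1, 0]))

    def test_children_bits_subset_of_parent_union(self):
        rng = np.random.default_rng(5)
        config = GAConfig(crossover_rate=0.5, seed=5)
        for _ in range(300):
            p1 = chrom(rng.integers(0, 2, 16))
            p2 = chrom(rng.integers(0, 2, 16))
            union = np.flatnonzero(p1 | p2)
            for child in crossover(p1, p2, config, rng):
                assert set(np.flatnonzero(child)) <= set(union)

    def test_mutation_rate_extremes(self):
        base = chrom([1, 0, 1, 0, 0, 0])
        unchanged = mutate(base, GAConfig(mutation_rate=0.0, seed=0))
        assert np.array_equal(unchanged, base)
        flipped = mutate(base, GAConfig(mutation_rate=1.0, seed=0))
        assert np.array_equal(flipped, 1 - base)

    def test_mutation_flip_count_is_binomial(self):
        rng = np.random.default_rng(6)
        config = GAConfig(mutation_rate=0.05, seed=6)
        base = chrom(np.zeros(32))
        base[:3] = 1
        flips = []
        for _ in range(10_000):
            flipped = np.where(rng.random(32) < 0.05, 1 - base, base)
            flips.append(int(np.sum(flipped != base)))
        # direct binomial Monte-Carlo: mean flips 32*0.05 = 1.6
        se = np.sqrt(32 * 0.05 * 0.95 / 10_000)
        assert abs(np.mean(flips) - 1.6) < 3 * se

    def test_repair_clears_random_excess_bits(self):
        rng = np.random.default_rng(7)
        full = chrom([1, 1, 1, 1, 1, 0, 0, 0])
        repaired = repair_cap(full, 3, rng)
        assert popcount(repaired) == 3
        assert set(np.flatnonzero(repaired)) <= set(np.flatnonzero(full))

    def test_repair_noop_and_floor(self):
        rng = np.random.default_rng(8)
        ok = chrom([1, 0, 1, 0])
        assert np.array_equal(repair_cap(ok, 3, rng), ok)
        assert popcount(repair_cap(chrom([0, 0, 0, 0]), 3, rng)) == 1


class TestSelection:
    def test_truncation_removes_lowest_half(self):
        config = GAConfig(population_size=10, truncation_fraction=0.5, elitism=2, seed=0)
        population = [chrom([1, 0, 0]) for _ in range(10)]
        fitnesses = [0.1, 0.9, 0.2, 0.8, 0.3, 0.7, 0.4, 0.6, 0.5, 0.95]
        survivors, pairs = select_survivors_and_parents(population, fitnesses, config)
        assert len(survivors) == 5
        assert len(pairs) == 4  # ceil((10-2)/2)

    def test_tie_break_prefers_fewer_bits_then_lexicographic(self):
        lean = chrom([0, 1, 0])
        fat = chrom([1, 0, 1])
        early = chrom([0, 0, 1])
        assert fitness_key(0.5, lean) < fitness_key(0.5, fat)
        assert fitness_key(0.5, early) < fitness_key(0.5, lean)
        assert fitness_key(0.6, fat) < fitness_key(0.5, lean)

    def test_population_collapse_rejected(self):
        config = GAConfig(population_size=4, truncation_fraction=0.8, elitism=0, seed=0)
        population = [chrom([1, 0])] * 4
        with pytest.raises(Exception, match="population collapse"):
            select_survivors_and_parents(population, [0.1] * 4, config)


class TestEvaluateChromosome:
    def test_cache_and_fixed_folds_give_identical_records(self, leak_table):
        config = GAConfig(cap=2, seed=1)
        c = chrom([1, 0, 0])
        a = evaluate_chromosome(c, leak_table, ("low_1",), LR, config)
        b = evaluate_chromosome(c, leak_table, ("low_1",), LR, config)
        assert a == b

    def test_label_leak_scores_near_one(self, leak_table):
        config = GAConfig(cap=1, seed=2)
        record = evaluate_chromosome(
            chrom([1, 0, 0]), leak_table, (), LR, config,
            selectable=("leak", "noise_1", "noise_2"),
        )
        assert record.mean_cv_score >= 0.99

    def test_mean_is_average_of_folds(self, leak_table):
        config = GAConfig(cv_folds=3, cap=2, seed=3)
        record = evaluate_chromosome(chrom([0, 1, 0]), leak_table, (), LR, config)
        assert record.mean_cv_score == pytest.approx(np.mean(record.per_fold_scores))
        assert len(record.per_fold_scores) == 3


class TestRunPga:
    def test_selects_planted_leak_at_cap_one(self, leak_table):
        from pgaselect import CostPartition

        partition = CostPartition(low_cost=("low_1",), high_cost=("leak", "noise_1", "noise_2"))
        config = GAConfig(population_size=20, max_generations=20, cap=1, seed=4)
        result = run_pga(leak_table, partition, (), LR, config)
        assert result.selected_high_cost == ("leak",)
        assert result.best_cv_score >= 0.99

    def test_history_best_is_non_decreasing(self, leak_table):
        from pgaselect import CostPartition

        partition = CostPartition(low_cost=("low_1",), high_cost=("leak", "noise_1", "noise_2"))
        config = GAConfig(population_size=12, max_generations=15, cap=2, elitism=1, seed=5)
        result = run_pga(leak_table, partition, ("low_1",), LR, config)
        best = result.history["best"].to_numpy()
        assert (np.diff(best) >= 0).all()

    def test_unconstrained_cap_dominates_cap_one(self, small_planted_cohort):
        cohort = small_planted_cohort
        partition = cohort.schema.partition(cohort.table.feature_names)
        scores = {}
        for cap in (1, len(partition.high_cost)):
            config = GAConfig(population_size=20, max_generations=15, cap=cap, seed=6)
            scores[cap] = run_pga(cohort.table, partition, (), LR, config).best_cv_score
        assert scores[len(partition.high_cost)] >= scores[1]

    def test_bit_identical_reproducibility(self, small_planted_cohort):
        cohort = small_planted_cohort
        partition = cohort.schema.partition(cohort.table.feature_names)
        config = GAConfig(population_size=15, max_generations=10, cap=3, seed=7)
        a = run_pga(cohort.table, partition, (), LR, config)
        b = run_pga(cohort.table, partition, (), LR, config)
        pd.testing.assert_frame_equal(a.history, b.history)
        assert a.selected_high_cost == b.selected_high_cost

    def test_empty_high_cost_rejected(self, leak_table):
        from pgaselect import CostPartition

        partition = CostPartition(low_cost=("low_1",), high_cost=())
        with pytest.raises(ValueError, match="high-cost"):
            run_pga(leak_table, partition, (), LR, GAConfig())


class TestStandardGa:
    def test_single_candidate_is_forced(self, leak_table):
        config = GAConfig(population_size=4, max_generations=2, elitism=1, seed=0)
        assert run_standard_ga(leak_table, ("noise_1",), LR, config) == ("noise_1",)

    def test_leak_beats_noise(self, leak_table):
        config = GAConfig(population_size=10, max_generations=10, seed=1)
        selected = run_standard_ga(leak_table, ("leak", "noise_1"), LR, config)
        assert "leak" in selected

    def test_determinism(self, leak_table):
        config = GAConfig(population_size=8, max_generations=5, seed=2)
        a = run_standard_ga(leak_table, ("leak", "noise_1", "noise_2"), LR, config)
        b = run_standard_ga(leak_table, ("leak", "noise_1", "noise_2"), LR, config)
        assert a == b


class TestTwoStage:
    def test_stage1_selection_becomes_fixed_set(self, leak_table):
        from pgaselect import CostPartition

        partition = CostPartition(
            low_cost=("low_1",), high_cost=("leak", "noise_1", "noise_2")
        )
        config = GAConfig(population_size=8, max_generations=5, seed=3)
        stage2 = GAConfig(population_size=8, max_generations=5, cap=2, seed=3)
        result = run_two_stage(leak_table, partition, LR, config, stage2)
        assert result.stage1_selected == ("low_1",)  # only candidate
        assert result.fixed_low_cost == result.stage1_selected

    def test_stage2_equals_direct_run_with_same_fixed_set(self, small_planted_cohort):
        """The staged result is the plain partial-GA run with stage 1's set fixed."""
        cohort = small_planted_cohort
        table = cohort.table
        # add two low-cost columns so stage 1 has something to select
        values = table.values.copy()
        rng = np.random.default_rng(0)
        values["low_a"] = rng.integers(0, 3, len(values)).astype(float)
        values["low_b"] = rng.integers(0, 3, len(values)).astype(float)
        from pgaselect import CostPartition, FeatureTable

        table2 = FeatureTable(values=values, label=table.label)
        partition = CostPartition(
            low_cost=("low_a", "low_b"), high_cost=tuple(table.feature_names)
        )
        stage1 = GAConfig(population_size=8, max_generations=4, seed=9)
        stage2 = GAConfig(population_size=10, max_generations=6, cap=3, seed=9)
        staged = run_two_stage(table2, partition, LR, stage1, stage2)
        direct = run_pga(table2, partition, staged.stage1_selected, LR, stage2)
        assert staged.selected_high_cost == direct.selected_high_cost
        pd.testing.assert_frame_equal(staged.history, direct.history)


class TestEstimatorProtocol:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        selector = PartialGeneticSelector(cap=4, population_size=12, random_state=3)
        cloned = clone(selector)
        assert cloned.get_params() == selector.get_params()

    def test_fit_transform_predict(self, leak_table):
        selector = PartialGeneticSelector(
            classifier=LR,
            fixed_features=("low_1",),
            selectable_features=("leak", "noise_1", "noise_2"),
            cap=1,
            population_size=10,
            max_generations=10,
            random_state=0,
        )
        X, y = leak_table.values, leak_table.label.to_numpy()
        selector.fit(X, y)
        assert selector.selected_features_ == ("leak",)
        transformed = selector.transform(X)
        assert list(transformed.columns) == ["low_1", "leak"]
        assert (selector.predict(X) == y).mean() >= 0.99

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            PartialGeneticSelector().predict(pd.DataFrame({"a": [1.0]}))
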