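import numpy as np
import pytest

from methylpanel.ga import (
    FitnessEvaluator,
    GAConfig,
    consensus_counts,
    consensus_panel,
    initialize_population,
    mutate,
    run_ga,
    tournament_select,
    two_point_crossover,
)
from methylpanel.io import ConfigurationError
from methylpanel.synthetic import SyntheticDesign, generate


SMALL = GAConfig(
    population_size=20, max_generations=8, elitism_count=2,
    burn_in_generation=3, panel_size=5, rf_n_trees=8, seed=0,
)


class TestConfigValidation:
    def test_study_defaults_are_valid(self):
        cfg = GAConfig()
        assert cfg.population_size == 100
        assert cfg.max_generations == 100
        assert cfg.tournament_size == 2
        assert cfg.elitism_count == 10
        assert cfg.crossover_prob == 0.6
        assert cfg.mutation_prob == 0.05
        assert cfg.init_fraction == 0.30

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"elitism_count": 100},
            {"crossover_prob": 1.5},
            {"burn_in_generation": 100},
            {"panel_size": 0},
            {"fitness_cv_folds": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GAConfig(**kwargs)


class TestInitialization:
    def test_exact_thirty_percent_of_candidates_set(self):
        rng = np.random.default_rng(0)
        pop = initialize_population(100, GAConfig(seed=0), rng)
        assert pop.shape == (100, 100)
        np.testing.assert_array_equal(pop.sum(axis=1), 30)

    def test_degenerate_fraction_repaired_to_one_bit(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(init_fraction=0.01)
        pop = initialize_population(10, cfg, rng)
        np.testing.assert_array_equal(pop.sum(axis=1), 1)

    def test_same_seed_identical_population(self):
        cfg = GAConfig()
        a = initialize_population(50, cfg, np.random.default_rng(3))
        b = initialize_population(50, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestTournament:
    def test_single_individual_population(self):
        idx = tournament_select(np.array([0.7]), GAConfig(), np.random.default_rng(0))
        assert idx == 0

    def test_higher_fitness_always_wins_pairwise(self):
        fitness = np.array([0.9, 0.6])
        rng = np.random.default_rng(1)
        for _ in range(200):
            winner = tournament_select(fitness, GAConfig(), rng)
            assert winner in (0, 1)
            # whenever both were drawn the better one wins; losing draws can
            # only be (1,1), so index 1 must never win more than chance allows
        wins = [tournament_select(fitness, GAConfig(), rng) for _ in range(2000)]
        assert np.mean(np.array(wins) == 1) == pytest.approx(0.25, abs=0.05)

    def test_selection_pressure_monotone_in_rank(self):
        fitness = np.linspace(0, 1, 10)
        rng = np.random.default_rng(2)
        counts = np.zeros(10)
        for _ in range(10_000):
            counts[tournament_select(fitness, GAConfig(), rng)] += 1
        assert (np.diff(counts) > 0).mean() > 0.8  # increasing with fitness
        assert counts[-1] > counts[0] * 5


class FakeRng:
    """Deterministic stand-in driving crossover to chosen cut points."""

    def __init__(self, cuts):
        self._cuts = np.array(cuts)

    def random(self):
        return 0.0  # always below crossover_prob

    def choice(self, a, size, replace):
        return self._cuts


class TestCrossover:
    def test_hand_worked_segment_swap(self):
        a = np.array([1, 1, 1, 1], dtype=bool)
        b = np.zeros(4, dtype=bool)
        c1, c2 = two_point_crossover(a, b, GAConfig(), FakeRng([1, 3]))
        np.testing.assert_array_equal(c1, [1, 0, 0, 1])
        np.testing.assert_array_equal(c2, [0, 1, 1, 0])

    def test_zero_probability_copies_parents(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(crossover_prob=0.0)
        a = np.array([1, 0, 1, 0, 1], dtype=bool)
        b = np.array([0, 1, 1, 0, 0], dtype=bool)
        c1, c2 = two_point_crossover(a, b, cfg, rng)
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, b)

    def test_per_locus_conservation(self):
        rng = np.random.default_rng(1)
        cfg = GAConfig()
        for _ in range(300):
            a = rng.random(12) < 0.5
            b = rng.random(12) < 0.5
            c1, c2 = two_point_crossover(a, b, cfg, rng)
            np.testing.assert_array_equal(
                c1.astype(int) + c2.astype(int), a.astype(int) + b.astype(int)
            )


class TestMutation:
    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(0)
        chrom = np.array([1, 0, 1], dtype=bool)
        np.testing.assert_array_equal(
            mutate(chrom, GAConfig(mutation_prob=0.0), rng), chrom
        )

    def test_probability_one_complements(self):
        rng = np.random.default_rng(0)
        chrom = np.array([1, 0, 1, 0], dtype=bool)
        np.testing.assert_array_equal(
            mutate(chrom, GAConfig(mutation_prob=1.0), rng), ~chrom
        )

    def test_all_zero_result_repaired(self):
        rng = np.random.default_rng(0)
        chrom = np.array([1, 1], dtype=bool)
        out = mutate(chrom, GAConfig(mutation_prob=1.0), rng)
        assert out.sum() == 1  # complement is empty, one bit restored

    def test_empirical_flip_rate_near_nominal(self):
        rng = np.random.default_rng(4)
        cfg = GAConfig(mutation_prob=0.05)
        chrom = np.zeros(100, dtype=bool)
        chrom[:50] = True
        flips = 0
        for _ in range(1000):
            flips += int((mutate(chrom, cfg, rng) ^ chrom).sum())
        assert 0.045 <= flips / 100_000 <= 0.055


@pytest.fixture(scope="module")
def ga_dataset():
    design = SyntheticDesign(
        n_normal=30, n_ln_neg=15, n_ln_pos=15, n_unclassified=0,
        n_probes_total=30, n_cancer_informative=6, n_ln_informative=0,
        n_redundant_per_informative=0, delta_cancer=0.3, concentration=5.0,
        seed=77,
    )
    matrix, pheno, truth = generate(design)
    labels = (pheno != "normal").astype(int).to_numpy()
    return matrix, labels, truth


class TestFitnessEvaluator:
    def test_perfectly_separating_probe_scores_one(self):
        X = np.concatenate([np.full((20, 1), 0.1), np.full((20, 1), 0.9)])
        y = np.array([0] * 20 + [1] * 20)
        evaluate = FitnessEvaluator(X, y, SMALL, rf_seed=1)
        assert evaluate(np.array([True])) == 1.0

    def test_permuted_labels_score_near_half(self):
        rng = np.random.default_rng(5)
        X = rng.random((200, 5))
        near_half = 0
        for s in range(8):
            y = rng.permutation([0, 1] * 100)
            evaluate = FitnessEvaluator(X, y, SMALL, rf_seed=s)
            if 0.4 <= evaluate(np.ones(5, dtype=bool)) <= 0.6:
                near_half += 1
        assert near_half >= 6

    def test_planted_probes_beat_null_probes(self, ga_dataset):
        matrix, labels, truth = ga_dataset
        X = matrix.to_numpy().T
        evaluate = FitnessEvaluator(X, labels, SMALL, rf_seed=3)
        probes = list(matrix.index)
        planted_mask = np.array([p in truth.cancer_informative_probes for p in probes])
        assert evaluate(planted_mask) > evaluate(~planted_mask)

    def test_deterministic_and_cached(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        X = matrix.to_numpy().T
        evaluate = FitnessEvaluator(X, labels, SMALL, rf_seed=3)
        chrom = np.zeros(X.shape[1], dtype=bool)
        chrom[:4] = True
        first = evaluate(chrom)
        assert evaluate(chrom) == first
        assert evaluate.n_evaluations == 1

    def test_empty_chromosome_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        y = np.array([0, 1] * 5)
        evaluate = FitnessEvaluator(X, y, SMALL, rf_seed=0)
        with pytest.raises(ValueError):
            evaluate(np.zeros(3, dtype=bool))


class TestRunGA:
    @staticmethod
    @pytest.fixture(scope="class")
    def trace(ga_dataset):
        matrix, labels, _ = ga_dataset
        return run_ga(matrix, labels, list(matrix.index), SMALL)

    def test_best_fitness_monotone_nondecreasing(self, trace):
        best = np.array(trace.best_fitness)
        assert (np.diff(best) >= -1e-12).all()

    def test_trace_length_and_population_bookkeeping(self, trace):
        assert trace.n_generations == SMALL.max_generations
        assert len(trace.best_chromosomes) == SMALL.max_generations
        for elites in trace.elite_chromosomes:
            assert 1 <= len(elites) <= SMALL.elitism_count

    def test_final_best_improves_on_initial_mean(self, trace):
        assert trace.best_fitness[-1] > trace.mean_fitness[0]

    def test_identical_seeds_identical_traces(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        t1 = run_ga(matrix, labels, list(matrix.index), SMALL)
        t2 = run_ga(matrix, labels, list(matrix.index), SMALL)
        assert t1.best_fitness == t2.best_fitness
        assert t1.mean_fitness == t2.mean_fitness
        for a, b in zip(t1.best_chromosomes, t2.best_chromosomes):
            np.testing.assert_array_equal(a, b)

    def test_too_few_candidates_rejected(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        with pytest.raises(ConfigurationError):
            run_ga(matrix, labels, [matrix.index[0]], SMALL)


class TestConsensus:
    def test_counts_bounded_by_collected_solutions(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        trace = run_ga(matrix, labels, list(matrix.index), SMALL)
        counts = consensus_counts(trace, SMALL)
        n_collected = sum(len(e) for e in trace.elite_chromosomes[SMALL.burn_in_generation:])
        assert counts.between(0, n_collected).all()
        present_everywhere = [
            p for i, p in enumerate(trace.candidates)
            if all(e[:, i].any() for e in trace.elite_chromosomes[SMALL.burn_in_generation:])
        ]
        window = len(trace.elite_chromosomes) - SMALL.burn_in_generation
        for p in present_everywhere:
            assert counts[p] >= window

    def test_panel_ordered_by_count_then_id(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        trace = run_ga(matrix, labels, list(matrix.index), SMALL)
        counts = consensus_counts(trace, SMALL)
        panel = consensus_panel(trace, SMALL, comparison="normal_vs_cancer")
        assert len(panel.probes) == SMALL.panel_size
        keys = [(-counts[p], p) for p in panel.probes]
        assert keys == sorted(keys)
        worst_in = max(counts[p] for p in panel.probes[-1:])
        best_out = counts.drop(list(panel.probes)).max()
        assert worst_in >= best_out or counts[panel.probes[-1]] == best_out

    def test_single_generation_window(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        trace = run_ga(matrix, labels, list(matrix.index), SMALL)
        late_burn = GAConfig(
            population_size=20, max_generations=8, elitism_count=2,
            burn_in_generation=7, panel_size=5, seed=0,
        )
        # burn-in 7 of 8 generations: counts come from the final elite set only
        counts = consensus_counts(trace, late_burn)
        assert counts.max() <= len(trace.elite_chromosomes[-1])
        final_best = trace.best_chromosomes[-1]
        for i, p in enumerate(trace.candidates):
            if final_best[i]:
                assert counts[p] >= 1

    def test_burn_in_exceeding_trace_rejected(self, ga_dataset):
        matrix, labels, _ = ga_dataset
        trace = run_ga(matrix, labels, list(matrix.index), SMALL)
        too_late = GAConfig(
            population_size=20, max_generations=20, elitism_count=2,
            burn_in_generation=10, panel_size=5, seed=0,
        )
        with pytest.raises(ConfigurationError):
            consensus_counts(trace, too_late)
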