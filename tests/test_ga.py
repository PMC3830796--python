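"""Genetic-algorithm operators and the generational search loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cefminer.ga import (
    FitnessConfig,
    GAConfig,
    Individual,
    evaluate_population,
    fitness,
    init_population,
    multipoint_crossover,
    run_ga,
    three_gene_swap,
    tournament_select,
)
from cefminer.records import ValidationError

from .conftest import make_table


class TestConfigs:
    def test_penalty_and_bounds_validated(self):
        with pytest.raises(ValidationError):
            FitnessConfig(R=-1)
        with pytest.raises(ValidationError):
            FitnessConfig(s_set=1.0)
        with pytest.raises(ValidationError):
            GAConfig(tournament_size=0)

    def test_large_k_makes_p_init_invalid(self):
        # k * n_set / m >= 1 filters out every feasible candidate
        cfg = GAConfig(k=4.0)
        with pytest.raises(ValidationError):
            cfg.p_init(m=30, n_set=8)


class TestInitPopulation:
    def test_size_and_gene_density(self):
        cfg = GAConfig(pop_size=1000, seed=0)
        rng = np.random.default_rng(0)
        pop = init_population(cfg, m=230, n_set=8, rng=rng)
        assert pop.shape == (1000, 230)
        p = 8 / 230
        ones = pop.sum()
        expected = 1000 * 230 * p
        sd = np.sqrt(1000 * 230 * p * (1 - p))
        assert abs(ones - expected) < 3 * sd

    def test_reproducible_given_seed(self):
        cfg = GAConfig(pop_size=50, seed=0)
        a = init_population(cfg, 20, 4, np.random.default_rng(9))
        b = init_population(cfg, 20, 4, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestFitness:
    def _table(self):
        X = np.zeros((50, 6), dtype=np.uint8)
        X[:10, :3] = 1          # ten records carry herbs 0-2
        X[10:, 3] = 1
        y = np.zeros(50, int)
        y[:6] = 1               # the formula group is enriched
        y[10:14] = 1
        return make_table(X, y)

    def test_feasible_candidate_scores_its_ev(self):
        t = self._table()
        f_cfg = FitnessConfig(R=200, n_set=2, level=1.0, s_set=0.1)
        ind = Individual(np.array([1, 1, 0, 0, 0, 0], dtype=np.uint8))
        f = fitness(ind, t, f_cfg)
        assert f > 0
        assert ind.fitness == f

    def test_infeasible_candidate_penalised_by_R(self):
        t = self._table()
        f_cfg = FitnessConfig(R=200, n_set=4, level=1.0, s_set=0.1)
        ind = Individual(np.array([1, 1, 1, 0, 0, 0], dtype=np.uint8))  # N=3 < 4
        f_pen = fitness(ind, t, f_cfg)
        f_cfg2 = FitnessConfig(R=200, n_set=3, level=1.0, s_set=0.1)
        f_ok = fitness(Individual(ind.chromosome.copy()), t, f_cfg2)
        assert f_pen == pytest.approx(f_ok - 200)

    def test_undefined_ev_maps_to_negative_sentinel(self):
        t = self._table()
        f_cfg = FitnessConfig(R=200, n_set=2, level=1.0, s_set=0.1)
        # herbs 0 and 3 never co-occur: empty group, EV undefined
        ind = Individual(np.array([1, 0, 0, 1, 0, 0], dtype=np.uint8))
        assert fitness(ind, t, f_cfg) == -200

    def test_penalty_dominance(self):
        """With R above max |EV|, every infeasible ranks below every feasible."""
        t = self._table()
        f_cfg = FitnessConfig(R=200, n_set=1, level=1.0, s_set=0.1)
        pop = np.array(
            [[1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 0, 0],
             [0, 1, 0, 0, 1, 0], [1, 0, 0, 1, 0, 0]],
            dtype=np.uint8,
        )
        fit, _ = evaluate_population(pop, t, f_cfg)
        sup = np.array([1, 1, 1, 0, 0], dtype=bool)  # which have support >= 0.1
        assert fit[sup].min() > fit[~sup].max()


class TestTournament:
    def test_full_draw_tends_to_best(self):
        fit = np.array([0.1, 0.9, 0.5, 0.3])
        rng = np.random.default_rng(0)
        winners = tournament_select(fit, tournament_size=50, rng=rng, n_winners=200)
        assert (winners == 1).mean() > 0.95

    def test_size_one_is_uniform(self):
        fit = np.array([0.1, 0.9, 0.5, 0.3])
        rng = np.random.default_rng(1)
        winners = tournament_select(fit, 1, rng, 8000)
        counts = np.bincount(winners, minlength=4) / 8000
        assert np.allclose(counts, 0.25, atol=0.03)

    def test_all_equal_fitness_uniform_tiebreak(self):
        fit = np.ones(5)
        rng = np.random.default_rng(2)
        winners = tournament_select(fit, 3, rng, 10000)
        counts = np.bincount(winners, minlength=5) / 10000
        assert np.allclose(counts, 0.2, atol=0.03)


class TestCrossover:
    def test_identical_parents_identical_children(self):
        rng = np.random.default_rng(0)
        a = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        c1, c2 = multipoint_crossover(a, a.copy(), 2, 1.0, rng)
        assert np.array_equal(c1, a) and np.array_equal(c2, a)

    def test_single_cut_complementary_parents(self):
        a = np.array([1, 1, 1, 0, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 0, 1, 1, 1], dtype=np.uint8)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            c1, c2 = multipoint_crossover(a, b, 1, 1.0, rng)
            if np.array_equal(c1, np.ones(6, dtype=np.uint8)):
                assert np.array_equal(c2, np.zeros(6, dtype=np.uint8))
                break
        else:
            pytest.fail("cut after locus 3 never drawn in 50 seeds")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    def test_per_locus_gene_conservation(self, seed, points):
        rng = np.random.default_rng(seed)
        m = 12
        a = (rng.random(m) < 0.5).astype(np.uint8)
        b = (rng.random(m) < 0.5).astype(np.uint8)
        c1, c2 = multipoint_crossover(a, b, points, 0.7, rng)
        for j in range(m):
            assert sorted([c1[j], c2[j]]) == sorted([a[j], b[j]])

    def test_too_many_points_rejected(self):
        rng = np.random.default_rng(0)
        a = np.zeros(4, dtype=np.uint8)
        with pytest.raises(ValidationError):
            multipoint_crossover(a, a, 4, 1.0, rng)


class TestThreeGeneSwap:
    def test_cyclic_permutation_of_values(self):
        # force known loci by seeding until the chosen loci are 0,1,2
        chrom = np.array([1, 0, 0, 0], dtype=np.uint8)
        seen = set()
        for seed in range(200):
            out = three_gene_swap(chrom, np.random.default_rng(seed))
            seen.add(tuple(out))
        # the one-bit can only move (values permuted), never duplicate
        assert all(sum(s) == 1 for s in seen)
        assert len(seen) > 1

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_popcount_invariant(self, seed):
        rng = np.random.default_rng(seed)
        chrom = (rng.random(20) < 0.4).astype(np.uint8)
        out = three_gene_swap(chrom, rng)
        assert out.sum() == chrom.sum()

    def test_equal_values_leave_chromosome_unchanged(self):
        chrom = np.ones(5, dtype=np.uint8)
        out = three_gene_swap(chrom, np.random.default_rng(0))
        assert np.array_equal(out, chrom)


class TestRunGA:
    def test_no_feasible_subset_returns_empty(self, tiny_planted_table):
        f_cfg = FitnessConfig(R=200, n_set=2, level=1.0, s_set=0.999)
        ga = GAConfig(pop_size=60, generations=10, tournament_size=3, seed=0)
        assert run_ga(tiny_planted_table, ga, f_cfg) == []

    def test_deterministic_given_seed(self, tiny_planted_table):
        f_cfg = FitnessConfig(R=200, n_set=2, level=1.0, s_set=0.1)
        ga = GAConfig(pop_size=100, generations=30, tournament_size=5, seed=7)
        r1 = run_ga(tiny_planted_table, ga, f_cfg)
        r2 = run_ga(tiny_planted_table, ga, f_cfg)
        assert [tuple(r.candidate.herb_indices()) for r in r1] == [
            tuple(r.candidate.herb_indices()) for r in r2
        ]
        assert [r.fitness for r in r1] == [r.fitness for r in r2]

    def test_population_size_constant_and_fitness_cached_consistently(
        self, tiny_planted_table
    ):
        f_cfg = FitnessConfig(R=200, n_set=2, level=1.0, s_set=0.1)
        ga = GAConfig(pop_size=80, generations=20, tournament_size=5, seed=3)
        res = run_ga(tiny_planted_table, ga, f_cfg)
        for r in res:
            refit, _ = evaluate_population(
                r.candidate.herb_bits[None, :], tiny_planted_table, f_cfg
            )
            assert r.fitness == pytest.approx(float(refit[0]))
            assert r.fitness > 0
        # deduplicated and sorted descending
        keys = [r.candidate.herb_bits.tobytes() for r in res]
        assert len(keys) == len(set(keys))
        fits = [r.fitness for r in res]
        assert fits == sorted(fits, reverse=True)

    def test_matches_exhaustive_optimum_on_tiny_vocabulary(
        self, tiny_planted_table
    ):
        import itertools as it

        f_cfg = FitnessConfig(R=200, n_set=3, level=1.0, s_set=0.1)
        subsets = np.array(
            list(it.product([0, 1], repeat=12)), dtype=np.uint8
        )[1:]
        brute, _ = evaluate_population(subsets, tiny_planted_table, f_cfg)
        best = brute.max()
        ga = GAConfig(pop_size=200, generations=60, tournament_size=5,
                      seed=0, elitism=True)
        res = run_ga(tiny_planted_table, ga, f_cfg)
        assert res and res[0].fitness == pytest.approx(float(best))
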