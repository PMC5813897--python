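"""Genetic-algorithm operator tests: selection probabilities, crossover
statistics, mutation closure, and oracle equivalence on enumerable
fitness landscapes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iirabm as m
from iirabm.ga import allele_diversity, random_chromosome, replicate_seeds
from iirabm.intervention import ALLELES


class TestTournamentSelect:
    def test_identical_population_returns_member(self, rng):
        pop = [np.ones(12)] * 5
        out = m.tournament_select(pop, [2.0] * 5, rng)
        np.testing.assert_array_equal(out, np.ones(12))

    def test_single_member_certain(self, rng):
        pop = [np.full(12, 5.0)]
        for _ in range(20):
            np.testing.assert_array_equal(
                m.tournament_select(pop, [1.0], rng), pop[0]
            )

    def test_two_member_probability_three_quarters(self, rng):
        # enumeration oracle: draws (A,A),(A,B),(B,A) -> A; (B,B) -> B, so
        # P(A) = 3/4; check by frequency over 1e5 trials
        a, b = np.zeros(12), np.ones(12)
        pop, fits = [a, b], [1.0, 3.0]
        wins = sum(
            m.tournament_select(pop, fits, rng)[0] == 0 for _ in range(100_000)
        )
        assert wins / 100_000 == pytest.approx(0.75, abs=0.01)

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            m.tournament_select([], [], rng)


class TestUniformCrossover:
    def test_identical_parents_breed_true(self, rng):
        p = rng.choice(ALLELES, 24)
        c1, c2 = m.uniform_crossover(p, p.copy(), rng)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_children_closed_over_parent_alleles(self, rng):
        for _ in range(1000):
            p1 = rng.choice(ALLELES, 12)
            p2 = rng.choice(ALLELES, 12)
            c1, c2 = m.uniform_crossover(p1, p2, rng)
            assert ((c1 == p1) | (c1 == p2)).all()
            # complementarity: where c1 took p1, c2 took p2
            np.testing.assert_array_equal(np.sort([c1, c2], 0), np.sort([p1, p2], 0))

    def test_hamming_distance_binomial_statistics(self, rng):
        # fully distinct parents of length 96: per-gene coin flip makes the
        # child1-vs-parent1 Hamming distance Binomial(96, 1/2)
        p1 = np.full(96, 0.05)
        p2 = np.full(96, 20.0)
        dists = []
        for _ in range(10_000):
            c1, _ = m.uniform_crossover(p1, p2, rng)
            dists.append(int((c1 != p1).sum()))
        mean = np.mean(dists)
        assert mean == pytest.approx(48, abs=3 * np.sqrt(96 * 0.25))
        assert np.var(dists) == pytest.approx(96 * 0.25, rel=0.15)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            m.uniform_crossover(np.ones(12), np.ones(24), rng)


class TestMutate:
    def test_rate_zero_identity(self, rng):
        g = rng.choice(ALLELES, 48)
        np.testing.assert_array_equal(m.mutate(g, 0.0, rng), g)

    def test_rate_one_redraws_uniformly(self, rng):
        # every gene redrawn; a redraw matches the old allele w.p. 1/9
        g = np.full(12, 5.0)
        unchanged = 0
        trials = 3000
        for _ in range(trials):
            out = m.mutate(g, 1.0, rng)
            unchanged += int((out == g).sum())
        frac = unchanged / (trials * 12)
        assert frac == pytest.approx(1 / 9, abs=0.02)

    @given(st.integers(0, 2**31 - 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=50)
    def test_output_always_valid_chromosome(self, seed, rate):
        rng = np.random.default_rng(seed)
        g = random_chromosome(24, rng)
        out = m.mutate(g, rate, rng)
        assert out.shape == g.shape
        assert all(any(np.isclose(x, a) for a in ALLELES) for x in out)


class TestFitness:
    def test_result_is_exact_sum_of_parts(self):
        fr = m.FitnessResult(np.array([10.0, 20.0]), np.array([1.0, 2.0]))
        assert fr.F == 33.0
        assert fr.n_replicates == 2

    def test_replicate_seeds_deterministic_and_bounded(self):
        s1 = replicate_seeds(42, 10)
        s2 = replicate_seeds(42, 10)
        assert s1 == s2
        assert len(set(s1)) == 10
        assert all(0 <= s < 2**31 for s in s1)
        assert replicate_seeds(43, 10) != s1

    def test_fitness_invariant_under_seed_permutation(self, tiny_params, tiny_constants):
        import iirabm.ga as ga

        snap = m.snapshot_at(tiny_params, 3, at_step=10, constants=tiny_constants)
        cfg = m.GAConfig(population_size=2, replicates=4, rng_seed=1)
        genes = np.full(12, 0.5)
        fr = m.evaluate_fitness(genes, snap, cfg, spacing_steps=10, duration_steps=8)
        # permuting the seed list permutes the replicate readouts only
        seeds = replicate_seeds(cfg.rng_seed, cfg.replicates)
        total = 0.0
        for s in reversed(seeds):
            w = snap.copy()
            w.reseed(s)
            sched = m.schedule_from_chromosome(genes, start_step=snap.t,
                                               spacing_steps=10, duration_steps=8)
            m.run_world(w, sched, max_steps=sched.final_stage_start + 100 - w.t)
            ob = m.observe(w)
            total += ob.oxygen_deficit + ob.infectious_load
        assert fr.F == pytest.approx(total, rel=1e-9)

    def test_absorbing_snapshot_rejected(self, tiny_world):
        tiny_world.damage[:] = 1.0
        from iirabm.world import step

        step(tiny_world)
        with pytest.raises(ValueError, match="absorbing"):
            m.evaluate_fitness(np.ones(12), tiny_world, m.GAConfig(population_size=2))


def _sum_abs_dist_fitness(target: float):
    def fit(genes: np.ndarray) -> float:
        return float(np.abs(genes - target).sum())

    return fit


class TestRunGA:
    def test_single_allele_space_returns_identity(self):
        cfg = m.GAConfig(population_size=4, generations=3, rng_seed=0)
        best, hist = m.run_ga(cfg, _sum_abs_dist_fitness(1.0), 12, alleles=(1.0,))
        np.testing.assert_array_equal(best, np.ones(12))

    def test_nine_point_space_matches_enumeration(self):
        # 2 genes x 3 alleles = 9 chromosomes; exhaustive optimum is (2, 2)
        alleles = (0.5, 2.0, 5.0)
        fit = _sum_abs_dist_fitness(2.0)
        space = list(itertools.product(alleles, repeat=2))
        brute = min(space, key=lambda g: fit(np.array(g)))
        assert brute == (2.0, 2.0)
        cfg = m.GAConfig(population_size=8, generations=20, rng_seed=7)
        best, _ = m.run_ga(cfg, fit, 2, alleles=alleles)
        assert tuple(best) == brute

    def test_twelve_gene_mock_recovers_optimum(self):
        cfg = m.GAConfig(population_size=40, generations=60, rng_seed=3)
        best, hist = m.run_ga(cfg, _sum_abs_dist_fitness(2.0), 12)
        np.testing.assert_array_equal(best, np.full(12, 2.0))

    def test_elitism_makes_best_monotone(self):
        cfg = m.GAConfig(population_size=20, generations=40, rng_seed=5,
                         elitism_count=1)
        _, hist = m.run_ga(cfg, _sum_abs_dist_fitness(2.0), 24)
        best = hist["best_F"].to_numpy()
        assert (np.diff(best) <= 0).all()

    def test_reproducible_history(self):
        cfg = m.GAConfig(population_size=10, generations=15, rng_seed=11)
        b1, h1 = m.run_ga(cfg, _sum_abs_dist_fitness(2.0), 12)
        b2, h2 = m.run_ga(cfg, _sum_abs_dist_fitness(2.0), 12)
        np.testing.assert_array_equal(b1, b2)
        assert h1.equals(h2)

    def test_oracle_equivalence_rate(self):
        # enumerable 81-point space: the GA should find the optimum in
        # nearly every seeded run
        alleles = (0.5, 2.0, 5.0)
        fit = _sum_abs_dist_fitness(2.0)
        hits = 0
        for seed in range(100):
            cfg = m.GAConfig(population_size=12, generations=25, rng_seed=seed)
            best, _ = m.run_ga(cfg, fit, 4, alleles=alleles)
            hits += int(fit(best) == 0.0)
        assert hits >= 95

    def test_config_validation(self):
        with pytest.raises(ValueError, match="even"):
            m.GAConfig(population_size=7)
        with pytest.raises(ValueError, match="replicates"):
            m.GAConfig(population_size=4, replicates=0)


def test_allele_diversity_bounds():
    pop = [np.full(12, 2.0)] * 6
    assert allele_diversity(pop) == pytest.approx(1 / 9)
    rng = np.random.default_rng(0)
    pop = [rng.choice(ALLELES, 12) for _ in range(200)]
    assert allele_diversity(pop) > 0.5
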