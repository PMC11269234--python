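import numpy as np
import pytest

from ictalemo.emo_nsga2 import (
    EAConfig,
    Individual,
    ObjectiveEvaluator,
    crowded_compare,
    crowding_distance,
    dominates,
    fast_non_dominated_sort,
    init_population,
    make_offspring,
    run_nsga2,
    select_solution,
)
from ictalemo.feature_extraction import FeatureMatrix
from ictalemo.signal_io import Label
from oracles import peel_fronts_brute_force


def _gaussian_fm(rng, n=60, d=24, n_informative=4, sep=4.0):
    """Small synthetic feature matrix: first n_informative columns carry the classes."""
    y = np.repeat([0, 1], n // 2)
    x = rng.standard_normal((n, d))
    x[:, :n_informative] += sep * y[:, None]
    labels = [Label.ICTAL if v else Label.NON_ICTAL for v in y]
    cols = [(1 + j // d, j % d + 1) for j in range(d)]
    return FeatureMatrix(values=x, columns=cols, row_labels=labels)


def _ranked(objs):
    pop = [Individual(mask=np.ones(4, dtype=bool), o1=int(a), o2=float(b)) for a, b in objs]
    fronts = fast_non_dominated_sort([p.objectives for p in pop])
    for r, front in enumerate(fronts, start=1):
        d = crowding_distance([pop[i].objectives for i in front])
        for i, dist in zip(front, d):
            pop[i].rank, pop[i].crowding = r, float(dist)
    return pop


class TestInitPopulation:
    def test_masks_nonempty_and_deterministic(self):
        a = init_population(10, 512, np.random.default_rng(3))
        b = init_population(10, 512, np.random.default_rng(3))
        assert all(ind.mask.sum() >= 1 for ind in a)
        assert all(np.array_equal(x.mask, y.mask) for x, y in zip(a, b))

    def test_mean_popcount_in_binomial_band(self):
        pop = init_population(1000, 512, np.random.default_rng(0))
        mean = np.mean([ind.mask.sum() for ind in pop])
        band = 3 * np.sqrt(512 * 0.25) / np.sqrt(1000)
        assert abs(mean - 256) <= 3 * np.sqrt(512 * 0.25)  # coarse per-spec band
        assert abs(mean - 256) <= 10 * band  # and a tighter sanity check on the mean


class TestDominance:
    def test_basic_cases(self):
        assert dominates((2, 3), (5, 5))
        assert not dominates((1, 5), (5, 1))
        assert not dominates((5, 1), (1, 5))
        assert not dominates((2, 2), (2, 2))
        assert dominates((2, 2), (2, 3))

    def test_antisymmetric_on_grid(self):
        pts = [(a, b) for a in range(4) for b in range(4)]
        for p in pts:
            for q in pts:
                assert not (dominates(p, q) and dominates(q, p))


class TestNonDominatedSort:
    def test_mutually_non_dominated_front(self):
        fronts = fast_non_dominated_sort([(1, 5), (2, 3), (3, 1)])
        assert fronts == [[0, 1, 2]]

    def test_dominated_point_forms_second_front(self):
        fronts = fast_non_dominated_sort([(1, 5), (2, 3), (3, 1), (5, 5)])
        assert sorted(fronts[0]) == [0, 1, 2]
        assert fronts[1] == [3]

    def test_matches_brute_force_peeling(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            objs = [tuple(rng.integers(0, 10, size=2)) for _ in range(n)]
            fast = [sorted(f) for f in fast_non_dominated_sort(objs)]
            brute = [sorted(f) for f in peel_fronts_brute_force(objs)]
            assert fast == brute


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 2)])))
        assert np.all(np.isinf(crowding_distance([(1, 2), (2, 1)])))

    def test_hand_computed_middle_point(self):
        d = crowding_distance([(0, 10), (5, 5), (10, 0)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_invariant_under_affine_objective_rescaling(self, rng):
        objs = rng.random((8, 2))
        base = crowding_distance(objs)
        moved = crowding_distance(objs * [100.0, 0.01] + [5.0, -3.0])
        finite = np.isfinite(base)
        assert np.array_equal(finite, np.isfinite(moved))
        assert np.allclose(base[finite], moved[finite], rtol=1e-9)

    def test_euclidean_variant_extremes_still_infinite(self):
        d = crowding_distance([(0, 10), (5, 5), (10, 0)], metric="euclidean")
        assert np.isinf(d[0]) and np.isinf(d[2]) and np.isfinite(d[1])


class TestCrowdedCompare:
    def test_rank_then_crowding(self, rng):
        pop = _ranked([(1, 5), (2, 3), (5, 5)])
        assert crowded_compare(pop[0], pop[2], rng) is pop[0]  # rank 1 beats rank 2
        a = Individual(mask=np.ones(4, bool), o1=1, o2=1.0, )
        a.rank, a.crowding = 1, np.inf
        b = Individual(mask=np.ones(4, bool), o1=1, o2=1.0)
        b.rank, b.crowding = 1, 1.3
        assert crowded_compare(a, b, rng) is a

    def test_unranked_rejected(self, rng):
        a = Individual(mask=np.ones(4, bool))
        with pytest.raises(RuntimeError):
            crowded_compare(a, a, rng)

    def test_full_tie_is_fair_coin(self):
        rng = np.random.default_rng(0)
        a = Individual(mask=np.ones(4, bool), o1=1, o2=1.0)
        b = Individual(mask=np.ones(4, bool), o1=1, o2=1.0)
        a.rank = b.rank = 1
        a.crowding = b.crowding = np.inf
        wins_a = sum(crowded_compare(a, b, rng) is a for _ in range(1000))
        assert 450 <= wins_a <= 550


class TestMakeOffspring:
    def _parents(self, rng, n=8, length=32):
        pop = init_population(n, length, rng)
        for i, ind in enumerate(pop):
            ind.o1, ind.o2 = int(ind.mask.sum()), float(i)
        fronts = fast_non_dominated_sort([p.objectives for p in pop])
        for r, front in enumerate(fronts, start=1):
            d = crowding_distance([pop[i].objectives for i in front])
            for i, dist in zip(front, d):
                pop[i].rank, pop[i].crowding = r, float(dist)
        return pop

    def test_null_variation_copies_parents(self, rng):
        parents = self._parents(rng)
        cfg = EAConfig(pop_size=8, n_generations=1, crossover_prob=0.0, mutation_prob_per_bit=0.0)
        offspring = make_offspring(parents, cfg, rng)
        assert len(offspring) == 8
        parent_masks = {p.mask.tobytes() for p in parents}
        assert all(o.mask.tobytes() in parent_masks for o in offspring)

    def test_mutation_one_flips_every_bit(self, rng):
        parents = self._parents(rng)
        cfg = EAConfig(pop_size=8, n_generations=1, crossover_prob=0.0, mutation_prob_per_bit=1.0)
        offspring = make_offspring(parents, cfg, rng)
        parent_inverses = {(~p.mask).tobytes() for p in parents if (~p.mask).any()}
        for o in offspring:
            assert o.mask.tobytes() in parent_inverses

    def test_offspring_never_empty(self, rng):
        parents = self._parents(rng, length=4)
        cfg = EAConfig(pop_size=8, n_generations=1, mutation_prob_per_bit=0.5)
        for _ in range(200):
            for o in make_offspring(parents, cfg, rng):
                assert o.mask.sum() >= 1


class TestObjectiveEvaluation:
    def test_o1_is_popcount_and_memoized(self, rng):
        fm = _gaussian_fm(rng)
        cfg = EAConfig(pop_size=4, n_generations=1, cv_iterations=3)
        evaluate = ObjectiveEvaluator(fm, cfg, cv_seed=0)
        full = evaluate(Individual(mask=np.ones(fm.n_features, bool)))
        assert full.o1 == fm.n_features
        single = evaluate(Individual(mask=np.eye(1, fm.n_features, 0, dtype=bool)[0]))
        assert single.o1 == 1
        calls = evaluate.n_cv_calls
        again = evaluate(Individual(mask=np.ones(fm.n_features, bool)))
        assert evaluate.n_cv_calls == calls  # cache hit
        assert again.o2 == full.o2


class TestRunAndSelect:
    def test_config_echo_and_front_non_domination(self, rng):
        fm = _gaussian_fm(rng)
        cfg = EAConfig(pop_size=6, n_generations=5, cv_iterations=3, seed=1)
        archive = run_nsga2(fm, cfg)
        assert archive.config.pop_size == 6 and archive.config.n_generations == 5
        objs = [ind.objectives for ind in archive.front]
        for a in objs:
            assert not any(dominates(b, a) for b in objs if b != a)
        assert archive.selected is not None and archive.selected.rank == 1

    def test_bit_for_bit_reproducible(self, rng):
        fm = _gaussian_fm(rng)
        cfg = EAConfig(pop_size=6, n_generations=4, cv_iterations=3, seed=5)
        a = run_nsga2(fm, cfg)
        b = run_nsga2(fm, cfg)
        assert len(a.individuals) == len(b.individuals)
        for x, y in zip(a.individuals, b.individuals):
            assert np.array_equal(x.mask, y.mask) and x.objectives == y.objectives
        assert np.array_equal(a.selected.mask, b.selected.mask)

    def test_best_error_non_increasing_with_fixed_splits(self, rng):
        fm = _gaussian_fm(rng, sep=1.0)
        cfg = EAConfig(pop_size=8, n_generations=10, cv_iterations=3, seed=2)
        archive = run_nsga2(fm, cfg)
        best = [rec["best_o2"] for rec in archive.history]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_recovers_planted_informative_features(self, rng):
        fm = _gaussian_fm(rng, n=60, d=24, n_informative=4)
        cfg = EAConfig(pop_size=12, n_generations=30, cv_iterations=5, seed=3)
        archive = run_nsga2(fm, cfg)
        full_o2 = ObjectiveEvaluator(fm, cfg, cv_seed=cfg.seed)(Individual(mask=np.ones(24, bool))).o2
        front = archive.front
        assert any(ind.o1 <= 12 and ind.o2 <= full_o2 for ind in front)

    def test_early_stop_halts_on_stagnant_front(self, rng):
        fm = _gaussian_fm(rng)
        cfg = EAConfig(pop_size=6, n_generations=50, cv_iterations=3, seed=1, early_stop_patience=3)
        archive = run_nsga2(fm, cfg)
        assert len(archive.history) <= 50

    def test_select_solution_singleton_and_dominant_crowding(self, rng):
        from ictalemo.emo_nsga2 import ParetoArchive

        lone = Individual(mask=np.ones(4, bool), o1=1, o2=1.0)
        lone.rank, lone.crowding = 1, np.inf
        archive = ParetoArchive(individuals=[lone], config=EAConfig(pop_size=4, n_generations=1))
        assert select_solution(archive, rng) is lone
        assert archive.selected is lone

        pop = [Individual(mask=np.ones(4, bool), o1=i, o2=float(i)) for i in range(3)]
        for p in pop:
            p.rank, p.crowding = 1, 0.5
        pop[1].crowding = 4.0
        archive = ParetoArchive(individuals=pop, config=EAConfig(pop_size=4, n_generations=1))
        for seed in range(20):
            assert select_solution(archive, np.random.default_rng(seed)) is pop[1]

    def test_select_solution_empty_front_rejected(self, rng):
        from ictalemo.emo_nsga2 import ParetoArchive

        archive = ParetoArchive(individuals=[], config=EAConfig(pop_size=4, n_generations=1))
        with pytest.raises(RuntimeError):
            select_solution(archive, rng)
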