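import numpy as np
import pytest

import eegsel as es
from eegsel.nsga2 import GAConfig, make_offspring, threshold


def brute_force_fronts(objs: np.ndarray) -> list[list[int]]:
    """O(P^2 * O) front peeling from the full pairwise domination matrix."""
    n = objs.shape[0]
    dom = [[es.dominates(objs[i], objs[j]) for j in range(n)] for i in range(n)]
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [j for j in remaining if not any(dom[i][j] for i in remaining)]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestDominates:
    def test_equal_vectors_do_not_dominate(self):
        assert not es.dominates([3.0, 2.0], [3.0, 2.0])

    def test_componentwise_better(self):
        assert es.dominates([3.0, 1.0], [4.0, 2.0])

    def test_incomparable(self):
        assert not es.dominates([3.0, 5.0], [4.0, 1.0])
        assert not es.dominates([4.0, 1.0], [3.0, 5.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            es.dominates([1.0], [1.0, 2.0])


class TestNondominatedSort:
    def test_single_individual(self):
        fronts = es.nondominated_sort(np.array([[1.0, 2.0]]))
        assert len(fronts) == 1 and list(fronts[0]) == [0]

    def test_two_individuals_one_dominating(self):
        fronts = es.nondominated_sort(np.array([[2.0, 2.0], [1.0, 1.0]]))
        assert [list(f) for f in fronts] == [[1], [0]]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        objs = rng.integers(0, 5, size=(40, 3)).astype(float)
        fronts = es.nondominated_sort(objs)
        flat = np.concatenate(fronts)
        assert sorted(flat) == list(range(40))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        o = int(rng.integers(2, 6))
        objs = rng.integers(0, 6, size=(n, o)).astype(float)  # ties likely
        got = [sorted(f.tolist()) for f in es.nondominated_sort(objs)]
        assert got == brute_force_fronts(objs)


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(es.crowding_distance(np.array([[1.0, 2.0]]))))
        assert np.all(np.isinf(es.crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]]))))

    def test_collinear_equally_spaced_middle_point(self):
        """Three equally spaced points on a 2-objective trade-off: the middle
        one accumulates a full normalized gap per objective."""
        front = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        dist = es.crowding_distance(front)
        assert np.isinf(dist[0]) and np.isinf(dist[2])
        assert dist[1] == pytest.approx(2.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        front = rng.random((7, 3))
        perm = rng.permutation(7)
        np.testing.assert_allclose(es.crowding_distance(front[perm]), es.crowding_distance(front)[perm])

    def test_degenerate_objective_contributes_nothing(self):
        front = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
        assert es.crowding_distance(front)[1] == pytest.approx(1.0)


class TestMakeOffspring:
    def _ranked(self, proxies):
        objs = np.column_stack([proxies.sum(axis=1), -proxies[:, 0]])
        fronts = es.nondominated_sort(objs)
        ranks = np.empty(len(proxies), dtype=int)
        crowd = np.empty(len(proxies))
        for r, idx in enumerate(fronts, 1):
            ranks[idx] = r
            crowd[idx] = es.crowding_distance(objs[idx])
        return ranks, crowd

    def test_no_variation_copies_tournament_winners(self):
        rng = np.random.default_rng(2)
        proxies = rng.random((8, 5))
        ranks, crowd = self._ranked(proxies)
        children = make_offspring(proxies, ranks, crowd, GAConfig(population=8, pc=0.0, pm=0.0), rng)
        parent_rows = {row.tobytes() for row in proxies}
        assert all(child.tobytes() in parent_rows for child in children)

    def test_identical_parents_breed_identical_children(self):
        rng = np.random.default_rng(3)
        proxies = np.tile(np.array([0.9, 0.1, 0.7, 0.2]), (6, 1))
        ranks = np.ones(6, dtype=int)
        crowd = np.full(6, np.inf)
        children = make_offspring(proxies, ranks, crowd, GAConfig(population=6, pc=0.9, pm=0.0), rng)
        np.testing.assert_allclose(children, proxies)

    def test_bitflip_mutation_matches_binomial_expectation(self):
        """Binary mode, pc=0, pm=1/C: flips per chromosome are Binomial(C, pm);
        the empirical mean Hamming distance over 10,000 children must sit
        within 3 standard errors of C * pm = 1."""
        c = 10
        pm = 1.0 / c
        parents = np.zeros((10_000, c))
        ranks = np.ones(10_000, dtype=int)
        crowd = np.full(10_000, np.inf)
        rng = np.random.default_rng(4)
        cfg = GAConfig(population=10_000, pc=0.0, pm=pm, representation="binary")
        children = make_offspring(parents, ranks, crowd, cfg, rng)
        hamming = (threshold(children) != threshold(parents[:1])).sum(axis=1)
        se = np.sqrt(c * pm * (1 - pm) / 10_000)
        assert abs(hamming.mean() - c * pm) < 3 * se

    def test_masked_genes_stay_off(self):
        rng = np.random.default_rng(5)
        proxies = rng.random((8, 6))
        mask = np.array([True, True, False, True, False, True])
        proxies[:, ~mask] = 0.0
        ranks, crowd = self._ranked(proxies)
        children = make_offspring(proxies, ranks, crowd, GAConfig(population=8), rng, mask=mask)
        assert not threshold(children)[:, ~mask].any()


def popcount_objective(weights):
    def evaluate(genes):
        return np.array([float(genes.sum()), float(weights[genes].sum() + 1.0 / (1.0 + genes.sum()))])

    return evaluate


class TestEvolve:
    def test_log_accounting_small(self):
        cfg = GAConfig(population=10, generations=5, seed=0)
        log = es.evolve(popcount_objective(np.arange(6) * 0.1), 6, cfg)
        assert log.n_offspring_evaluations == 50
        assert log.n_evaluations == 60  # + initial population at generation 0
        assert set(log.frame["generation"]) == set(range(6))

    def test_bit_identical_reruns(self):
        cfg = GAConfig(population=12, generations=8, seed=42)
        evaluate = popcount_objective(np.random.default_rng(0).random(9))
        a = es.evolve(evaluate, 9, cfg)
        b = es.evolve(evaluate, 9, cfg)
        assert a.frame.equals(b.frame)
        np.testing.assert_array_equal(a.history, b.history)

    def test_elitism_keeps_population_minima_monotone(self):
        cfg = GAConfig(population=20, generations=30, seed=7)
        log = es.evolve(popcount_objective(np.random.default_rng(1).random(12)), 12, cfg)
        diffs = np.diff(log.history, axis=0)
        assert np.all(diffs <= 1e-12)

    def test_mask_respected_in_every_generation(self):
        cfg = GAConfig(population=10, generations=10, seed=1)
        mask = np.array([True] * 5 + [False] * 3)
        log = es.evolve(popcount_objective(np.random.default_rng(2).random(8)), 8, cfg, mask=mask)
        for bits in log.frame["chromosome"]:
            assert set(bits[5:]) <= {"0"}

    def test_full_chromosome_seeded_into_generation_zero(self):
        cfg = GAConfig(population=10, generations=1, seed=3)
        log = es.evolve(popcount_objective(np.zeros(7)), 7, cfg)
        gen0 = log.frame[log.frame["generation"] == 0]
        assert "1111111" in set(gen0["chromosome"])

    def test_log_round_trips_through_tsv(self, tmp_path):
        cfg = GAConfig(population=10, generations=3, seed=9)
        log = es.evolve(popcount_objective(np.random.default_rng(3).random(5)), 5, cfg)
        path = tmp_path / "log.tsv"
        log.to_tsv(path)
        loaded = es.CandidateLog.from_tsv(path)
        assert loaded.meta["seed"] == "9"
        assert len(loaded.frame) == len(log.frame)
        assert list(loaded.frame["chromosome"]) == list(log.frame["chromosome"])

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population=9)
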