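"""Unit and property tests for the genetic-search and tabu-search operators."""

import math

import numpy as np
import pytest

from mfmicd import (
    BinaryNetwork,
    GAParams,
    Partition,
    calibrated_fitness,
    convergence_rate,
    decode_partition,
    dynamic_rates,
    immune_operator,
    initialize_population,
    modularity,
    mutate,
    roulette_select,
    run_mfmicd,
    run_mfmicd_repeated,
    strongest_first_crossover,
    tabu_local_search,
)
from mfmicd.community import CONVERGED, Chromosome, Population
from mfmicd.errors import InvalidInputError, InvalidParameterError


def _pop_from_labels(labels_list, fitness):
    members = [Chromosome(np.asarray(l, dtype=np.int64)) for l in labels_list]
    return Population(
        members=members,
        raw_q=np.asarray(fitness, dtype=float),
        fitness=np.asarray(fitness, dtype=float),
    )


class TestInitialization:
    def test_edgeless_graph_gives_singletons(self):
        net = BinaryNetwork.from_edges(5, [])
        pop = initialize_population(net, 4, np.random.default_rng(0))
        for c in pop.members:
            assert list(c.labels) == [0, 1, 2, 3, 4]

    def test_complete_graph_labels_stay_in_node_set(self):
        net = BinaryNetwork.from_edges(3, [(0, 1), (0, 2), (1, 2)])
        pop = initialize_population(net, 10, np.random.default_rng(1))
        for c in pop.members:
            assert set(c.labels) <= {0, 1, 2}

    def test_labels_never_cross_components(self, two_triangles):
        # neighbor-copy can only propagate ids within a connected component
        rng = np.random.default_rng(7)
        for _ in range(100):
            pop = initialize_population(two_triangles, 10, rng)
            for c in pop.members:
                assert set(c.labels[:3]) <= {0, 1, 2}
                assert set(c.labels[3:]) <= {3, 4, 5}

    def test_rejects_tiny_population(self, two_triangles):
        with pytest.raises(InvalidParameterError):
            initialize_population(two_triangles, 1, np.random.default_rng(0))


class TestDecode:
    @pytest.mark.parametrize(
        "labels,expected_groups",
        [
            ([5, 5, 9, 9], ((0, 1), (2, 3))),
            ([1, 2, 3], ((0,), (1,), (2,))),
            ([7, 7, 7], ((0, 1, 2),)),
        ],
    )
    def test_examples(self, labels, expected_groups):
        p = decode_partition(Chromosome(np.asarray(labels)))
        assert p.groups == expected_groups


class TestFitnessCalibration:
    def test_shift_by_minimum(self):
        out = calibrated_fitness(np.array([-0.1, 0.2, 0.5]))
        assert np.allclose(out, [0.0, 0.3, 0.6])

    def test_degenerate_all_equal(self):
        assert np.allclose(calibrated_fitness(np.array([0.4, 0.4])), [0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_min_is_zero(self, seed):
        raw = np.random.default_rng(seed).normal(size=20)
        out = calibrated_fitness(raw)
        assert out.min() == pytest.approx(0.0)
        assert np.all(out >= 0)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            calibrated_fitness(np.array([]))


class TestRates:
    def test_convergence_rate_examples(self):
        f = np.array([1.0, 2.0, 3.0])
        assert convergence_rate((f.mean(), f.max(), f.min())) == pytest.approx(1.0)
        assert convergence_rate((0.5, 1.0, 0.0)) == pytest.approx(0.5)
        assert convergence_rate((2.0, 2.0, 2.0)) == CONVERGED

    def test_dynamic_rates_midpoint(self):
        params = GAParams(pm_bounds=(0.001, 0.999), pc_bounds=(0.001, 0.999))
        pc, pm = dynamic_rates(1.0, params)
        assert pm == pytest.approx(0.5)
        assert pc == pytest.approx(0.5)

    def test_dynamic_rates_clamps(self):
        params = GAParams()  # pm in [0.01, 0.5]
        pc, pm = dynamic_rates(0.0, params)
        assert pm == pytest.approx(0.5)  # 1/(0+1)=1 clamped to upper bound
        pc2, pm2 = dynamic_rates(CONVERGED, params)
        assert pm2 == pytest.approx(0.01)  # converged -> lower bound

    @pytest.mark.parametrize("phi", [0.2, 1.0, 3.0, 10.0])
    def test_complementary_when_unclamped(self, phi):
        params = GAParams(pm_bounds=(0.001, 0.999), pc_bounds=(0.001, 0.999))
        pc, pm = dynamic_rates(phi, params)
        assert pc + pm == pytest.approx(1.0)


class TestRouletteSelection:
    def test_uniform_for_equal_fitness(self):
        idx = roulette_select(np.array([2.0, 2.0, 2.0, 2.0]), 4000, np.random.default_rng(0))
        freq = np.bincount(idx, minlength=4) / 4000
        assert np.allclose(freq, 0.25, atol=0.03)

    def test_proportional_frequencies(self):
        # fitness [1, 3] -> probabilities [0.25, 0.75]
        idx = roulette_select(np.array([1.0, 3.0]), 100_000, np.random.default_rng(42))
        freq = np.bincount(idx, minlength=2) / 100_000
        assert abs(freq[0] - 0.25) < 0.01
        assert abs(freq[1] - 0.75) < 0.01

    def test_all_zero_fitness_uniform(self):
        idx = roulette_select(np.zeros(3), 3000, np.random.default_rng(1))
        freq = np.bincount(idx, minlength=3) / 3000
        assert np.allclose(freq, 1 / 3, atol=0.05)

    def test_negative_fitness_raises(self):
        with pytest.raises(InvalidInputError):
            roulette_select(np.array([1.0, -0.1]), 1, np.random.default_rng(0))


class TestCrossover:
    def test_pc_zero_copies_parents(self):
        pop = _pop_from_labels([[0, 1, 2], [2, 1, 0]], [0.5, 0.2])
        out = strongest_first_crossover(pop, 0.0, np.random.default_rng(0))
        assert [list(c.labels) for c in out] == [[0, 1, 2], [2, 1, 0]]

    def test_identical_parents_fixed_point(self):
        pop = _pop_from_labels([[1, 1, 2, 2]] * 4, [0.1] * 4)
        out = strongest_first_crossover(pop, 1.0, np.random.default_rng(3))
        for c in out:
            assert list(c.labels) == [1, 1, 2, 2]

    def test_wraparound_segment_hand_trace(self, monkeypatch):
        # cuts (4, 1) on length-6 strings: child A takes positions {4,5,0} from B
        from mfmicd.community import _circular_segment

        seg = _circular_segment(6, 4, 1)
        assert sorted(seg) == [0, 4, 5]
        pa = np.array([0, 0, 0, 0, 0, 0])
        pb = np.array([1, 1, 1, 1, 1, 1])
        ca = pa.copy()
        ca[seg] = pb[seg]
        assert list(ca) == [1, 0, 0, 0, 1, 1]

    def test_odd_population_copies_last(self):
        pop = _pop_from_labels([[0, 1], [1, 0], [0, 0]], [0.9, 0.5, 0.1])
        out = strongest_first_crossover(pop, 0.0, np.random.default_rng(0))
        assert len(out) == 3
        assert list(out[-1].labels) == [0, 0]

    def test_pairs_by_descending_fitness(self):
        # with pc=1 the two fittest exchange a segment with each other only
        pop = _pop_from_labels(
            [[9, 9, 9, 9], [5, 5, 5, 5], [7, 7, 7, 7], [3, 3, 3, 3]],
            [0.1, 0.9, 0.8, 0.2],
        )
        out = strongest_first_crossover(pop, 1.0, np.random.default_rng(0))
        union_top = set(out[0].labels) | set(out[1].labels)
        assert union_top <= {5, 7}  # members 1 and 2 paired first


class TestMutation:
    def test_pm_zero_identity(self, two_triangles):
        c = Chromosome(np.array([0, 1, 2, 3, 4, 5]))
        out = mutate(c, 0.0, two_triangles, np.random.default_rng(0))
        assert list(out.labels) == [0, 1, 2, 3, 4, 5]

    def test_edgeless_graph_identity(self):
        net = BinaryNetwork.from_edges(4, [])
        c = Chromosome(np.array([3, 1, 2, 0]))
        out = mutate(c, 1.0, net, np.random.default_rng(0))
        assert list(out.labels) == [3, 1, 2, 0]

    @pytest.mark.parametrize("seed", range(20))
    def test_new_label_comes_from_closed_neighborhood(self, seed, bridged_triangles):
        rng = np.random.default_rng(seed)
        adj = bridged_triangles.adjacency_lists()
        old = rng.integers(0, 6, size=6)
        out = mutate(Chromosome(old.copy()), 0.7, bridged_triangles, rng)
        for i in range(6):
            allowed = {old[i]} | {old[j] for j in adj[i]}
            assert out.labels[i] in allowed


class TestImmuneOperator:
    def test_identical_population_noop(self, two_triangles):
        labels = [0, 0, 0, 3, 3, 3]
        q = modularity(two_triangles, Partition.from_labels(labels))
        pop = _pop_from_labels([labels] * 6, [q] * 6)
        out = immune_operator(pop, two_triangles, np.random.default_rng(0))
        for c in out.members:
            assert list(c.labels) == labels

    @pytest.mark.parametrize("seed", range(10))
    def test_best_q_never_decreases(self, seed, bridged_triangles):
        rng = np.random.default_rng(seed)
        pop = initialize_population(bridged_triangles, 10, rng)
        u, v = bridged_triangles.edge_arrays()
        from mfmicd.metrics import modularity_from_labels

        pop.raw_q = np.array(
            [
                modularity_from_labels(
                    c.labels, u, v, bridged_triangles.degrees(), bridged_triangles.n_edges
                )
                for c in pop.members
            ]
        )
        before = pop.raw_q.max()
        out = immune_operator(pop, bridged_triangles, rng)
        assert out.raw_q.max() >= before - 1e-12

    def test_vaccination_helps_on_planted_graph(self, two_triangles):
        # one member holds the planted labels; injecting its high-degree
        # assignments should not lower mean Q (Monte-Carlo over seeds)
        from mfmicd.metrics import modularity_from_labels

        u, v = two_triangles.edge_arrays()
        deg, m = two_triangles.degrees(), two_triangles.n_edges
        deltas = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            members = [rng.integers(0, 6, size=6) for _ in range(7)]
            members.append(np.array([0, 0, 0, 3, 3, 3]))  # planted optimum
            qs = [modularity_from_labels(l, u, v, deg, m) for l in members]
            pop = _pop_from_labels(members, qs)
            out = immune_operator(pop, two_triangles, rng)
            deltas.append(out.raw_q.mean() - pop.raw_q.mean())
        assert np.mean(deltas) >= 0.0


class TestTabuSearch:
    def test_optimum_is_fixed_point(self, two_triangles, triangle_partition):
        out = tabu_local_search(two_triangles, triangle_partition, GAParams())
        assert modularity(two_triangles, out) == pytest.approx(0.5)
        assert out == triangle_partition

    def test_climbs_from_singletons(self, two_triangles, triangle_partition):
        start = Partition.from_labels(range(6))
        out = tabu_local_search(two_triangles, start, GAParams(max_gen_tabu=20))
        assert out == triangle_partition

    def test_never_worse_than_feasible_start(self, bridged_triangles):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            start = Partition.from_labels(rng.integers(0, 3, size=6))
            q0 = modularity(bridged_triangles, start)
            out = tabu_local_search(bridged_triangles, start, GAParams())
            # guarantee holds when the start has no disconnected community
            from mfmicd.community import _disconnected_communities

            if _disconnected_communities(start.labels(), bridged_triangles.adjacency_lists()) == 0:
                assert modularity(bridged_triangles, out) >= q0 - 1e-12

    def test_lambda_zero_ignores_penalty(self, two_triangles):
        # disconnected-community start: {0,3} spans both triangles
        start = Partition.from_labels([0, 1, 1, 0, 2, 2])
        params = GAParams(lambda_penalty=0.0)
        out = tabu_local_search(two_triangles, start, params)
        assert modularity(two_triangles, out) >= modularity(two_triangles, start)


class TestFullRun:
    def test_two_triangles_exact(self, two_triangles, triangle_partition):
        res = run_mfmicd(two_triangles, GAParams(pop_size=20, max_gen_global=10, seed=0))
        assert res.best_q == pytest.approx(0.5)
        assert res.best_partition == triangle_partition

    def test_best_q_consistent_with_independent_recompute(self, bridged_triangles):
        res = run_mfmicd(bridged_triangles, GAParams(pop_size=20, max_gen_global=10, seed=1))
        assert res.best_q == pytest.approx(
            modularity(bridged_triangles, res.best_partition), abs=1e-12
        )

    def test_elitism_trace_nondecreasing(self, bridged_triangles):
        res = run_mfmicd(bridged_triangles, GAParams(pop_size=20, max_gen_global=15, seed=2))
        best = [row["best_q"] for row in res.trace]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_reproducible_from_seed(self, bridged_triangles):
        params = GAParams(pop_size=20, max_gen_global=10, seed=123)
        r1 = run_mfmicd(bridged_triangles, params)
        r2 = run_mfmicd(bridged_triangles, params)
        assert r1.best_partition == r2.best_partition
        assert r1.best_q == r2.best_q
        assert r1.trace == r2.trace

    def test_repeated_runs_report_stability(self, two_triangles):
        params = GAParams(pop_size=20, max_gen_global=10, seed=5, runs_per_setting=3)
        res = run_mfmicd_repeated(two_triangles, params)
        assert res.stability_nmi == pytest.approx(1.0)
        assert res.best_q == pytest.approx(0.5)
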