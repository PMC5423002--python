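"""Engine tests: lattice topology, operators, accounting, convergence."""

import numpy as np
import pytest

from fcmgrn import EngineParams, GeneratorConfig, generate_fcm, generate_sequences
from fcmgrn.core import SubMapProblem
from fcmgrn.dmaga import (
    L9,
    BudgetExhausted,
    CountingObjective,
    assign_neighbor_counts,
    candidate_neighbors,
    golden_section,
    optimize_submap,
    orthogonal_candidates,
    self_learning,
    strategy1,
    strategy2,
    submap_error_fn,
)


def _problem(n_nodes=5, ns=5, nt=4, seed=7, density=0.4, node=1):
    config = GeneratorConfig(
        n_nodes=n_nodes, edge_density=density, n_sequences=ns, n_time=nt, seed=seed
    )
    truth = generate_fcm(config)
    data = generate_sequences(truth, config)
    return truth, SubMapProblem(
        node_index=node, incoming_weights=np.zeros(n_nodes), data=data
    )


class TestLattice:
    def test_corner_cell_wraps(self):
        assert candidate_neighbors(1, 1, 5) == {(5, 1), (1, 5), (1, 2), (2, 1)}

    def test_interior_cell(self):
        assert candidate_neighbors(3, 3, 5) == {(2, 3), (3, 2), (3, 4), (4, 3)}

    @pytest.mark.parametrize("lsize", [3, 4, 5])
    def test_regular_and_symmetric(self, lsize):
        for a in range(1, lsize + 1):
            for b in range(1, lsize + 1):
                nbrs = candidate_neighbors(a, b, lsize)
                assert len(nbrs) == 4
                for cell in nbrs:
                    assert (a, b) in candidate_neighbors(*cell, lsize)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            candidate_neighbors(0, 1, 5)


class TestLevels:
    def test_even_split_sixteen(self, rng):
        counts = assign_neighbor_counts(rng.normal(size=16))
        values, freq = np.unique(counts, return_counts=True)
        assert dict(zip(values, freq)) == {1: 4, 2: 4, 3: 4, 4: 4}

    def test_remainder_goes_to_top_level(self, rng):
        counts = assign_neighbor_counts(rng.normal(size=25))
        values, freq = np.unique(counts, return_counts=True)
        assert dict(zip(values, freq)) == {1: 6, 2: 6, 3: 6, 4: 7}

    def test_extremes(self, rng):
        energies = rng.normal(size=25)
        counts = assign_neighbor_counts(energies)
        assert counts[np.argmin(energies)] == 1
        assert counts[np.argmax(energies)] == 4

    def test_ties_broken_by_position(self):
        counts = assign_neighbor_counts(np.zeros(8))
        np.testing.assert_array_equal(counts, [4, 4, 3, 3, 2, 2, 1, 1])


class _FixedRng:
    """Stub generator returning a constant for uniform draws."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        return self.value if size is None else np.full(size, self.value)


class TestStrategies:
    def test_strategy1_hand_example(self):
        out = strategy1(np.array([0.3]), np.array([0.5]), _FixedRng(1.0))
        assert out[0] == pytest.approx(0.7, abs=1e-15)

    def test_strategy1_clips(self):
        out = strategy1(np.array([-0.9]), np.array([0.9]), _FixedRng(1.0))
        assert out[0] == 1.0  # 0.9 + 1.8 clipped

    def test_strategy1_identical_parents(self, rng):
        g = rng.uniform(-1, 1, 6)
        np.testing.assert_array_equal(strategy1(g, g, rng), g)

    def test_strategy2_segment_reversal(self):
        genome = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        out = strategy2(genome, k=2, s=5)
        np.testing.assert_allclose(out, [0.1, 0.5, 0.4, 0.3, 0.2, 0.6])

    def test_strategy2_is_involution(self, rng):
        g = rng.uniform(-1, 1, 8)
        np.testing.assert_array_equal(strategy2(strategy2(g, 3, 6), 3, 6), g)

    def test_strategy2_preserves_multiset(self, rng):
        g = rng.uniform(-1, 1, 7)
        np.testing.assert_array_equal(
            np.sort(strategy2(g, 2, 6)), np.sort(g)
        )

    @pytest.mark.parametrize("k,s", [(1, 3), (2, 2), (3, 2), (2, 6)])
    def test_strategy2_invalid_bounds(self, k, s):
        with pytest.raises(ValueError):
            strategy2(np.zeros(6), k, s)


class TestOrthogonalCrossover:
    def test_l9_is_an_orthogonal_array(self):
        for col in range(4):
            assert sorted(L9[:, col]) == [0, 0, 0, 1, 1, 1, 2, 2, 2]
        for c1 in range(4):
            for c2 in range(c1 + 1, 4):
                pairs = {(a, b) for a, b in zip(L9[:, c1], L9[:, c2])}
                assert len(pairs) == 9  # every level combination appears

    def test_identical_parents_give_identical_candidates(self, rng):
        g = rng.uniform(-1, 1, 10)
        cands = orthogonal_candidates(g, g)
        assert np.all(cands == g)

    def test_candidates_match_array_rows(self, rng):
        # N=4: each factor group is a single coordinate, so candidate r
        # component g must be levels[L9[r, g]] exactly
        parent, partner = rng.uniform(-1, 1, 4), rng.uniform(-1, 1, 4)
        levels = [parent, partner, 0.5 * (parent + partner)]
        cands = orthogonal_candidates(parent, partner)
        for r in range(9):
            expected = [levels[L9[r, g]][g] for g in range(4)]
            np.testing.assert_array_equal(cands[r], expected)

    def test_candidate_values_come_from_parents(self, rng):
        parent, partner = rng.uniform(-1, 1, 11), rng.uniform(-1, 1, 11)
        cands = orthogonal_candidates(parent, partner)
        mid = 0.5 * (parent + partner)
        for r in range(9):
            ok = (cands[r] == parent) | (cands[r] == partner) | (cands[r] == mid)
            assert ok.all()


class TestGoldenSection:
    def test_quadratic_minimum(self):
        x, fx = golden_section(lambda x: (x - 0.3) ** 2, tol=1e-3, max_evals=40)
        assert x == pytest.approx(0.3, abs=1e-3)

    def test_respects_eval_cap(self):
        calls = []
        golden_section(lambda x: calls.append(x) or x**2, tol=0.0, max_evals=20)
        assert len(calls) == 20


class TestAccounting:
    def test_counts_every_row(self):
        obj = CountingObjective(lambda W: np.zeros(W.shape[0]), budget=100)
        obj.errors(np.zeros((7, 3)))
        obj.error_one(np.zeros(3))
        assert obj.calls == 8
        assert obj.remaining == 92

    def test_refuses_overrun(self):
        obj = CountingObjective(lambda W: np.zeros(W.shape[0]), budget=5)
        obj.errors(np.zeros((4, 2)))
        with pytest.raises(BudgetExhausted):
            obj.errors(np.zeros((2, 2)))
        assert obj.calls == 4  # refused batch never counted

    def test_optimize_counts_objective_calls(self, monkeypatch):
        import fcmgrn.dmaga as dmaga

        counter = {"rows": 0}
        original = dmaga.submap_error_fn

        def counting(data, node_index, lam):
            fn = original(data, node_index, lam)

            def wrapped(W):
                counter["rows"] += np.atleast_2d(W).shape[0]
                return fn(W)

            return wrapped

        monkeypatch.setattr(dmaga, "submap_error_fn", counting)
        _, problem = _problem()
        params = EngineParams(eval_budget=2000, seed=1)
        result = optimize_submap(problem, params)
        assert result.evaluations_used == counter["rows"]
        assert result.evaluations_used <= 2000

    def test_budget_below_population_rejected(self):
        _, problem = _problem()
        with pytest.raises(ValueError):
            optimize_submap(problem, EngineParams(eval_budget=10))


class TestSelfLearning:
    def test_recovers_single_weight(self):
        # one-node self-regulating map: a 1-D problem where a dense grid
        # search over [-1, 1] is the oracle
        from fcmgrn.core import SequenceSet, WeightMatrix, simulate

        truth = WeightMatrix(weights=np.array([[-0.6]]))
        traj = simulate(truth, np.array([0.8]), n_time=10)
        data = SequenceSet(sequences=(traj,))
        fn = submap_error_fn(data, 1)
        grid = np.linspace(-1, 1, 4001)
        x_oracle = grid[np.argmin(fn(grid[:, None]))]

        obj = CountingObjective(fn, budget=10_000)
        start = np.array([0.0])
        refined, err = self_learning(
            start, obj.error_one(start), obj, np.random.default_rng(0),
            max_evals_per_coord=40,
        )
        assert refined[0] == pytest.approx(x_oracle, abs=1e-3)

    def test_never_worsens_energy(self, rng):
        _, problem = _problem()
        fn = submap_error_fn(problem.data, 1)
        obj = CountingObjective(fn, budget=10_000)
        for _ in range(5):
            g = rng.uniform(-1, 1, 5)
            before = obj.error_one(g)
            _, after = self_learning(g, before, obj, rng)
            assert after <= before


class TestOptimizeSubmap:
    def test_solves_noise_free_small_problem(self):
        truth, problem = _problem(node=2)
        params = EngineParams(eval_budget=30_000, seed=0)
        result = optimize_submap(problem, params)
        assert result.best_error <= 5e-4
        assert np.all(np.abs(result.best_genome) <= 1.0)

    def test_trace_monotone_nondecreasing(self):
        _, problem = _problem(node=3)
        result = optimize_submap(problem, EngineParams(eval_budget=5000, seed=2))
        assert np.all(np.diff(result.trace) >= 0)

    def test_same_seed_bit_identical(self):
        _, problem = _problem(node=1)
        params = EngineParams(eval_budget=4000, seed=9)
        a = optimize_submap(problem, params)
        b = optimize_submap(problem, params)
        np.testing.assert_array_equal(a.best_genome, b.best_genome)
        np.testing.assert_array_equal(a.trace, b.trace)
        assert a.evaluations_used == b.evaluations_used

    def test_three_node_problem_runs(self):
        # dimension 3 admits no valid reversal segment; blend must kick in
        _, problem = _problem(n_nodes=3, density=0.4, node=1)
        result = optimize_submap(problem, EngineParams(eval_budget=3000, seed=4))
        assert result.best_error < 0.25

    def test_selection_pressure_favours_top_level(self, rng):
        # Monte-Carlo on the decision rule: an agent survives only when it
        # strictly beats the best of its sampled neighbours, so bottom-level
        # agents must be replaced more often than top-level agents.
        from fcmgrn.dmaga import _flat_neighbors

        adjacency = _flat_neighbors(5)
        replaced = {1: 0, 4: 0}
        tried = {1: 0, 4: 0}
        for _ in range(200):
            energies = rng.normal(size=25)
            counts = assign_neighbor_counts(energies)
            for p in range(25):
                if counts[p] not in replaced:
                    continue
                sampled = rng.choice(adjacency[p], size=counts[p], replace=False)
                tried[counts[p]] += 1
                if energies[p] <= energies[sampled].max():
                    replaced[counts[p]] += 1
        rate_bottom = replaced[1] / tried[1]
        rate_top = replaced[4] / tried[4]
        assert rate_bottom > rate_top
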