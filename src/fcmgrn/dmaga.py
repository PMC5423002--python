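"""Dynamical multi-agent genetic algorithm (dMAGA) for per-node FCM learning.

Each candidate incoming-weight vector is an *agent* living on a fixed
``Lsize x Lsize`` toroidal lattice.  An agent's energy is the negative of its
node data error (higher is better; 0 only at a perfect fit).  One generation
consists of four phases:

1. **Dynamic neighbourhoods** — agents are ranked by energy and split into
   four levels (ties broken by lattice position, remainders assigned to the
   higher levels).  Agents in the top level sample 4 of their lattice
   neighbours to compete against, the next levels 3, 2 and 1.  Weak agents
   thus face fewer competitors, which softens selection pressure and
   preserves diversity.
2. **Neighbourhood competition** — an agent that is strictly better than the
   best of its sampled neighbours (``Max``) survives unchanged; otherwise it
   is replaced, with probability ``p_o`` by a blend ``Max + U(-1,1)*(Max -
   agent)`` per component (clipped to [-1, 1]), and otherwise by ``Max`` with
   a random internal segment reversed.  The segment bounds ``(k, s)`` must
   satisfy ``1 < k < s < N``; genomes of dimension <= 3 admit no such pair
   and always use the blend.
3. **Crossover and mutation** — with probability ``p_c`` an agent undergoes
   orthogonal crossover against the best of its four lattice neighbours: the
   genome is split into four contiguous factor groups, each taking one of
   three levels (parent value, neighbour value, midpoint), combined per the
   L9(3^4) orthogonal array; the best of the nine candidates replaces the
   parent if strictly better.  With probability ``p_m`` each agent proposes a
   componentwise Gaussian perturbation (sigma 0.1, clipped), accepted only on
   improvement.
4. **Self-learning** — the current generation's best agent refines itself by
   a coordinatewise golden-section line search over [-1, 1] (random
   coordinate order, tolerance 1e-3, at most 20 evaluations per coordinate),
   keeping each coordinate's best found value.

Every energy evaluation is counted; a run stops when the evaluation budget is
exhausted, when the best energy has not improved for ``stagnation_patience``
generations, or when the best error drops below ``target_error``.  Competition
decisions within a generation are taken synchronously against the
generation-start energies, which lets replacements be evaluated in one batch.

The same engine, applied to the flattened ``N^2``-dimensional whole-matrix
problem, serves as the in-repo monolithic baseline
(:func:`optimize_full_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import expit

from .core import DEFAULT_LAMBDA, SequenceSet, SubMapProblem, WeightMatrix

__all__ = [
    "L9",
    "EngineParams",
    "OptimizeResult",
    "BudgetExhausted",
    "CountingObjective",
    "submap_error_fn",
    "full_matrix_error_fn",
    "candidate_neighbors",
    "assign_neighbor_counts",
    "strategy1",
    "strategy2",
    "orthogonal_candidates",
    "golden_section",
    "self_learning",
    "optimize_submap",
    "optimize_full_matrix",
]

DEFAULT_TOTAL_BUDGET = 1_500_000

# L9(3^4) orthogonal array, levels coded 0/1/2: every column carries each
# level three times and every column pair carries all nine level combinations.
L9 = np.array(
    [
        [0, 0, 0, 0],
        [0, 1, 1, 1],
        [0, 2, 2, 2],
        [1, 0, 1, 2],
        [1, 1, 2, 0],
        [1, 2, 0, 1],
        [2, 0, 2, 1],
        [2, 1, 0, 2],
        [2, 2, 1, 0],
    ]
)


@dataclass(frozen=True)
class EngineParams:
    """Tunable knobs of the engine.

    ``eval_budget`` is the per-problem cap on energy evaluations; when
    ``None`` it is resolved as ``total_budget // n_nodes`` so that a full
    N-node training run stays within ``total_budget`` evaluations overall.
    """

    lsize: int = 5
    p_o: float = 0.2
    p_c: float = 0.1
    p_m: float = 0.1
    lam: float = DEFAULT_LAMBDA
    eval_budget: int | None = None
    total_budget: int = DEFAULT_TOTAL_BUDGET
    stagnation_patience: int = 50
    min_rel_improvement: float = 1e-3
    target_error: float = 1e-10
    mutation_sigma: float = 0.1
    self_learning_tol: float = 1e-3
    self_learning_max_evals: int = 20
    self_learning_local_window: float = 0.02
    self_learning_max_coords: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lsize < 2:
            raise ValueError("lsize must be >= 2")
        for name in ("p_o", "p_c", "p_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.total_budget < 1:
            raise ValueError("total_budget must be positive")
        if self.stagnation_patience < 1:
            raise ValueError("stagnation_patience must be >= 1")
        if not 0.0 <= self.min_rel_improvement < 1.0:
            raise ValueError("min_rel_improvement must lie in [0, 1)")
        if self.mutation_sigma < 0:
            raise ValueError("mutation_sigma must be >= 0")

    @property
    def population(self) -> int:
        return self.lsize * self.lsize

    def resolve_budget(self, n_nodes: int) -> int:
        budget = self.eval_budget
        if budget is None:
            budget = self.total_budget // n_nodes
        if budget < self.population:
            raise ValueError(
                f"eval_budget {budget} smaller than the lattice population "
                f"{self.population}"
            )
        return int(budget)


@dataclass(frozen=True)
class OptimizeResult:
    """Outcome of one engine run on one problem."""

    best_genome: np.ndarray
    best_energy: float
    evaluations_used: int
    generations: int
    trace: np.ndarray  # all-time best energy after each generation

    @property
    def best_error(self) -> float:
        return -self.best_energy


class BudgetExhausted(Exception):
    """Raised internally when an evaluation batch would overrun the budget."""


class CountingObjective:
    """Wraps a batched error function with evaluation accounting.

    ``fn`` maps a ``(P, D)`` genome block to ``(P,)`` errors; every row costs
    one evaluation.  A batch that would exceed the budget is refused (raising
    :class:`BudgetExhausted`) so the counter can never overshoot.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], budget: int):
        self._fn = fn
        self.budget = int(budget)
        self.calls = 0

    @property
    def remaining(self) -> int:
        return self.budget - self.calls

    def errors(self, genomes: np.ndarray) -> np.ndarray:
        block = np.atleast_2d(np.asarray(genomes, dtype=float))
        if block.shape[0] > self.remaining:
            raise BudgetExhausted
        self.calls += block.shape[0]
        return np.asarray(self._fn(block), dtype=float)

    def error_one(self, genome: np.ndarray) -> float:
        return float(self.errors(genome[None, :])[0])


def submap_error_fn(
    data: SequenceSet, node_index: int, lam: float = DEFAULT_LAMBDA
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched per-node data error: genomes ``(P, N)`` -> errors ``(P,)``.

    Precomputes the stacked teacher-forcing design once; each evaluation is a
    single matrix product plus a sigmoid.
    """
    X, Y = data.transitions()
    Xl = lam * X
    y = Y[:, node_index - 1]

    def fn(genomes: np.ndarray) -> np.ndarray:
        preds = expit(genomes @ Xl.T)  # (P, M)
        return np.mean((preds - y) ** 2, axis=1)

    return fn


def full_matrix_error_fn(
    data: SequenceSet, lam: float = DEFAULT_LAMBDA
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched whole-map data error on flattened ``N^2`` genomes.

    Genome layout: row-major ``(N, N)``, i.e. component ``j*N + i`` is the
    weight of edge ``j -> i``.  Used by the monolithic baseline.
    """
    X, Y = data.transitions()
    Xl = lam * X
    n = data.n_nodes

    def fn(genomes: np.ndarray) -> np.ndarray:
        out = np.empty(genomes.shape[0])
        for p in range(genomes.shape[0]):
            preds = expit(Xl @ genomes[p].reshape(n, n))
            out[p] = np.mean((preds - Y) ** 2)
        return out

    return fn


def candidate_neighbors(a: int, b: int, lsize: int) -> set[tuple[int, int]]:
    """The four toroidal lattice neighbours of 1-based cell ``(a, b)``.

    Up/left wrap to ``lsize`` at index 1; down/right wrap to 1 at ``lsize``.
    """
    if not (1 <= a <= lsize and 1 <= b <= lsize):
        raise ValueError(f"cell ({a}, {b}) outside 1..{lsize}")
    up = lsize if a == 1 else a - 1
    left = lsize if b == 1 else b - 1
    down = 1 if a == lsize else a + 1
    right = 1 if b == lsize else b + 1
    return {(up, b), (a, left), (a, right), (down, b)}


def assign_neighbor_counts(energies: np.ndarray) -> np.ndarray:
    """Per-agent competitor count in {1..4} from an energy ranking.

    Agents are sorted by decreasing energy (ties broken by position, i.e.
    row-major flat index) and split into four levels; when the population is
    not divisible by 4 the remainder goes to the higher levels.  Level 1
    (best) gets 4 competitors, level 4 (worst) gets 1.
    """
    energies = np.asarray(energies, dtype=float)
    n = energies.shape[0]
    order = np.argsort(-energies, kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if lvl < rem else 0) for lvl in range(4)]
    counts = np.empty(n, dtype=int)
    start = 0
    for lvl, size in enumerate(sizes):
        counts[order[start : start + size]] = 4 - lvl
        start += size
    return counts


def strategy1(
    loser: np.ndarray, winner: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Blend replacement: per component ``m + U(-1,1)*(m - l)``, clipped.

    Keeps some information from the defeated agent; identical parents yield
    the winner unchanged.
    """
    loser = np.asarray(loser, dtype=float)
    winner = np.asarray(winner, dtype=float)
    if loser.shape != winner.shape:
        raise ValueError("genome lengths differ")
    u = rng.uniform(-1.0, 1.0, size=winner.shape[0])
    return np.clip(winner + u * (winner - loser), -1.0, 1.0)


def strategy2(winner: np.ndarray, k: int, s: int) -> np.ndarray:
    """Segment-reversal replacement: winner with positions ``k..s`` reversed.

    ``k`` and ``s`` are 1-based and must satisfy ``1 < k < s < N`` strictly,
    so the first and last components always stay in place.
    """
    winner = np.asarray(winner, dtype=float)
    n = winner.shape[0]
    if not (1 < k < s < n):
        raise ValueError(f"(k, s) = ({k}, {s}) violates 1 < k < s < {n}")
    out = winner.copy()
    out[k - 1 : s] = winner[k - 1 : s][::-1]
    return out


def _draw_segment(dim: int, rng: np.random.Generator) -> tuple[int, int]:
    # uniform over pairs 2 <= k < s <= dim - 1 (1-based)
    k, s = np.sort(rng.choice(np.arange(2, dim), size=2, replace=False))
    return int(k), int(s)


def orthogonal_candidates(parent: np.ndarray, partner: np.ndarray) -> np.ndarray:
    """The nine L9(3^4) crossover candidates between two genomes.

    The genome is split into four contiguous factor groups (trailing groups
    may be empty for very short genomes); factor levels are parent value,
    partner value and their midpoint.
    """
    parent = np.asarray(parent, dtype=float)
    partner = np.asarray(partner, dtype=float)
    if parent.shape != partner.shape:
        raise ValueError("genome lengths differ")
    dim = parent.shape[0]
    groups = np.array_split(np.arange(dim), 4)
    levels = (parent, partner, 0.5 * (parent + partner))
    cands = np.empty((9, dim))
    for r, row in enumerate(L9):
        for g, lvl in enumerate(row):
            idx = groups[g]
            cands[r, idx] = levels[lvl][idx]
    return cands


def golden_section(
    f: Callable[[float], float],
    lo: float = -1.0,
    hi: float = 1.0,
    tol: float = 1e-3,
    max_evals: int = 20,
) -> tuple[float, float]:
    """Minimise a 1-D function on ``[lo, hi]``; returns ``(x_best, f_best)``.

    Standard golden-section bracketing; stops when the bracket is narrower
    than ``tol`` or ``max_evals`` function calls have been spent.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = f(c), f(d)
    evals = 2
    while (hi - lo) > tol and evals < max_evals:
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = f(d)
        evals += 1
    return (c, fc) if fc < fd else (d, fd)


def self_learning(
    genome: np.ndarray,
    error: float,
    objective: CountingObjective,
    rng: np.random.Generator,
    tol: float = 1e-3,
    max_evals_per_coord: int = 20,
    local_window: float = 0.02,
    max_coords: int | None = None,
) -> tuple[np.ndarray, float]:
    """Coordinatewise golden-section refinement of one genome.

    Visits coordinates in a random order (optionally a random subset of size
    ``max_coords``), line-searching each over [-1, 1] with the others held
    fixed.  A second golden-section pass over a narrow window of width
    ``2 * local_window`` around the coordinate's current value sharpens the
    bracket well below ``tol``, which is what lets runs on noise-free data
    reach the convergence target instead of plateauing at the coarse-search
    floor.  A coordinate's best value is kept only when it strictly improves
    the error; the returned error is never worse than the input error.
    """
    genome = np.asarray(genome, dtype=float).copy()
    start = genome.copy()
    dim = genome.shape[0]
    coords = rng.permutation(dim)
    if max_coords is not None:
        coords = coords[:max_coords]
    for j in coords:
        def f(x: float, _j=int(j)) -> float:
            trial = genome.copy()
            trial[_j] = x
            return objective.error_one(trial)

        x_best, f_best = golden_section(
            f, tol=tol, max_evals=max_evals_per_coord
        )
        if f_best < error:
            genome[j] = x_best
            error = f_best
        if local_window > 0:
            centre = genome[j]
            x_loc, f_loc = golden_section(
                f,
                lo=max(-1.0, centre - local_window),
                hi=min(1.0, centre + local_window),
                tol=0.0,
                max_evals=max_evals_per_coord,
            )
            if f_loc < error:
                genome[j] = x_loc
                error = f_loc

    # Powell-style acceleration: one extra line search along the sweep's net
    # displacement, which follows narrow valleys that axis-aligned moves
    # traverse only by slow zigzagging
    direction = genome - start
    if np.any(direction != 0.0):
        with np.errstate(divide="ignore"):
            limits = np.where(
                direction > 0,
                (1.0 - genome) / np.where(direction != 0, direction, 1.0),
                (-1.0 - genome) / np.where(direction != 0, direction, 1.0),
            )
        t_max = float(min(limits[direction != 0].min(), 10.0))
        if t_max > 0:
            def f_dir(t: float) -> float:
                return objective.error_one(genome + t * direction)

            t_best, f_best = golden_section(
                f_dir, lo=0.0, hi=t_max, tol=0.0, max_evals=max_evals_per_coord
            )
            if f_best < error:
                genome = np.clip(genome + t_best * direction, -1.0, 1.0)
                error = f_best
    return genome, error


def _flat_neighbors(lsize: int) -> np.ndarray:
    """(P, 4) array of flat candidate-neighbour indices, row-major cells.

    Keeps all four up/left/right/down slots even when they coincide (which
    happens only on a 2x2 lattice), so sampling weights stay uniform.
    """
    out = np.empty((lsize * lsize, 4), dtype=int)
    for a in range(1, lsize + 1):
        for b in range(1, lsize + 1):
            up = lsize if a == 1 else a - 1
            left = lsize if b == 1 else b - 1
            down = 1 if a == lsize else a + 1
            right = 1 if b == lsize else b + 1
            out[(a - 1) * lsize + (b - 1)] = [
                (up - 1) * lsize + (b - 1),
                (a - 1) * lsize + (left - 1),
                (a - 1) * lsize + (right - 1),
                (down - 1) * lsize + (b - 1),
            ]
    return out


def _best_of(indices: np.ndarray, errors: np.ndarray) -> int:
    """Index (from ``indices``) with minimal error; ties to lowest position."""
    indices = np.sort(np.asarray(indices))
    return int(indices[np.argmin(errors[indices])])


def _optimize(
    error_fn: Callable[[np.ndarray], np.ndarray],
    dim: int,
    params: EngineParams,
    budget: int,
    seed_seq: np.random.SeedSequence,
) -> OptimizeResult:
    rng = np.random.default_rng(seed_seq)
    obj = CountingObjective(error_fn, budget)
    pop = params.population
    adjacency = _flat_neighbors(params.lsize)

    genomes = rng.uniform(-1.0, 1.0, size=(pop, dim))
    errors = obj.errors(genomes)
    best_idx = int(np.argmin(errors))
    best_genome = genomes[best_idx].copy()
    best_error = float(errors[best_idx])
    trace = [-best_error]

    generations = 0
    stagnation = 0
    while (
        best_error > params.target_error
        and stagnation < params.stagnation_patience
        and obj.remaining > 0
    ):
        generations += 1
        try:
            # --- dynamic neighbourhood levels (start-of-generation energies)
            counts = assign_neighbor_counts(-errors)

            # --- neighbourhood competition (synchronous) ------------------
            repl_pos: list[int] = []
            repl_genomes: list[np.ndarray] = []
            for p in range(pop):
                sampled = rng.choice(adjacency[p], size=counts[p], replace=False)
                mx = _best_of(sampled, errors)
                if errors[p] < errors[mx]:  # strictly higher energy: survive
                    continue
                if dim <= 3 or rng.uniform() < params.p_o:
                    child = strategy1(genomes[p], genomes[mx], rng)
                else:
                    k, s = _draw_segment(dim, rng)
                    child = strategy2(genomes[mx], k, s)
                repl_pos.append(p)
                repl_genomes.append(child)
            if repl_pos:
                new_errors = obj.errors(np.asarray(repl_genomes))
                for p, g, e in zip(repl_pos, repl_genomes, new_errors):
                    genomes[p] = g
                    errors[p] = e

            # --- orthogonal crossover -------------------------------------
            selected = np.flatnonzero(rng.uniform(size=pop) < params.p_c)
            if selected.size:
                blocks = []
                partners = []
                for p in selected:
                    mx = _best_of(adjacency[p], errors)
                    partners.append(mx)
                    blocks.append(orthogonal_candidates(genomes[p], genomes[mx]))
                cand_errors = obj.errors(np.vstack(blocks))
                for i, p in enumerate(selected):
                    block = blocks[i]
                    errs = cand_errors[9 * i : 9 * (i + 1)]
                    j = int(np.argmin(errs))
                    if errs[j] < errors[p]:  # elitist acceptance
                        genomes[p] = block[j]
                        errors[p] = errs[j]

            # --- Gaussian mutation ----------------------------------------
            selected = np.flatnonzero(rng.uniform(size=pop) < params.p_m)
            if selected.size and params.mutation_sigma > 0:
                proposals = np.clip(
                    genomes[selected]
                    + rng.normal(0.0, params.mutation_sigma, size=(selected.size, dim)),
                    -1.0,
                    1.0,
                )
                prop_errors = obj.errors(proposals)
                improved = prop_errors < errors[selected]
                genomes[selected[improved]] = proposals[improved]
                errors[selected[improved]] = prop_errors[improved]

            # --- self-learning on the generation best ---------------------
            b = int(np.argmin(errors))
            refined, refined_error = self_learning(
                genomes[b],
                float(errors[b]),
                obj,
                rng,
                tol=params.self_learning_tol,
                max_evals_per_coord=params.self_learning_max_evals,
                local_window=params.self_learning_local_window,
                max_coords=params.self_learning_max_coords,
            )
            genomes[b] = refined
            errors[b] = refined_error
        except BudgetExhausted:
            pass

        gen_best = int(np.argmin(errors))
        if errors[gen_best] < best_error:
            # elitism: the all-time best always tracks any strict improvement,
            # but only a material (relative) improvement resets the stagnation
            # clock, so runs do not linger on float-level creep
            if errors[gen_best] < best_error * (1.0 - params.min_rel_improvement):
                stagnation = 0
            else:
                stagnation += 1
            best_error = float(errors[gen_best])
            best_genome = genomes[gen_best].copy()
        else:
            stagnation += 1
        trace.append(-best_error)

    return OptimizeResult(
        best_genome=best_genome,
        best_energy=-best_error,
        evaluations_used=obj.calls,
        generations=generations,
        trace=np.asarray(trace),
    )


def _node_seed(root_seed: int, node_index: int) -> np.random.SeedSequence:
    # spawn-key derivation: depends only on (root seed, node), never on the
    # order in which sub-problems are optimized
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(node_index,))


def optimize_submap(problem: SubMapProblem, params: EngineParams) -> OptimizeResult:
    """Learn one node's incoming-weight column with the lattice engine.

    The RNG stream is derived from ``params.seed`` and the node index alone,
    so per-node runs are reproducible and independent of execution order.
    """
    if problem.data is None:
        raise ValueError("SubMapProblem carries no data")
    n = problem.n_nodes
    budget = params.resolve_budget(n)
    fn = submap_error_fn(problem.data, problem.node_index, params.lam)
    return _optimize(fn, n, params, budget, _node_seed(params.seed, problem.node_index))


def optimize_full_matrix(
    data: SequenceSet, params: EngineParams, budget: int | None = None
) -> tuple[WeightMatrix, OptimizeResult]:
    """Monolithic baseline: run the same engine on the whole N^2 genome.

    Provided for budget-matched comparison against the decomposed trainer;
    the coordinatewise self-learning pass is capped at 50 random coordinates
    per generation so a single generation cannot swallow the whole budget.
    Returns the learned matrix and the raw engine result.
    """
    n = data.n_nodes
    if budget is None:
        budget = params.total_budget
    if params.self_learning_max_coords is None:
        params = replace(params, self_learning_max_coords=min(n * n, 50))
    if budget < params.population:
        raise ValueError("budget smaller than the lattice population")
    fn = full_matrix_error_fn(data, params.lam)
    result = _optimize(
        fn,
        n * n,
        params,
        budget,
        np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)),
    )
    learned = WeightMatrix(weights=result.best_genome.reshape(n, n))
    return learned, result
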