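# Methods

## Model

A fuzzy cognitive map (FCM) over `N` nodes (genes) is a signed weighted
digraph with weight matrix `w ∈ [-1, 1]^{N×N}`, where `w[j, i]` is the causal
strength of the edge `j → i` (positive = excitatory, negative = inhibitory,
zero = absent; self-loops allowed). Node activations `C^t ∈ [0, 1]^N` evolve
synchronously in discrete time:

    C_i^{t+1} = g( Σ_j w_ji · C_j^t ),    g(x) = 1 / (1 + exp(-λx))

`λ` (default 5, configurable) sets the slope of the logistic transfer; the
logistic is the standard FCM transfer function and the only one offered here.
Incoming weights of node `i` form column `i` of the matrix. Because published
FCM matrices use both orientations, the readers/writers expose a `transpose`
flag; the in-memory convention is fixed as row = source.

## Learning objective and decomposition

Given `Ns` observed response sequences with `Nt` time points each, the
training objective is the mean squared one-step-ahead prediction error under
teacher forcing (each prediction is driven by the *observed* previous state):

    Data_Error(w) = 1 / (N · Ns · (Nt-1)) Σ_n Σ_s Σ_t ( C_n^{t+1}(s) − Ĉ_n^{t+1}(s) )²

Under teacher forcing the prediction for node `i` depends only on column `i`,
so the objective decomposes exactly into the mean of `N` independent
per-node errors. Training therefore solves `N` problems of dimension `N`
instead of one of dimension `N²`; the per-node optima are assembled
column-wise into the learned matrix, and the whole-map error of the assembly
equals the mean of the per-node optima to float precision (asserted at 1e-12
in the tests).

## The lattice optimiser

Each candidate incoming-weight vector is an agent on a fixed `Lsize × Lsize`
torus (default 5×5 = 25 agents, initialised uniformly in `[-1,1]^N`). Agent
energy is the negative per-node data error. Per generation:

1. **Dynamic neighbourhoods.** Agents are ranked by energy (ties broken by
   lattice position, row-major) and split into four levels, remainders going
   to the higher levels (25 agents → 7/6/6/6). Top-level agents sample 4 of
   their four lattice neighbours to compete against; the next levels sample
   3, 2, 1. Weaker agents face fewer competitors, softening selection
   pressure.
2. **Competition.** An agent strictly better than the best sampled neighbour
   (`Max`) survives; otherwise it is replaced — with probability `p_o` (0.2)
   by the componentwise blend `Max + U(-1,1)·(Max − agent)` clipped to
   `[-1,1]`, else by `Max` with a random internal segment reversed (segment
   bounds `1 < k < s < N` strict; dimensions ≤ 3 admit none and always
   blend). Decisions are taken synchronously against generation-start
   energies so all offspring are evaluated in one batch.
3. **Orthogonal crossover** (probability `p_c` = 0.1 per agent) against the
   best of the agent's four lattice neighbours: the genome is split into four
   contiguous factor groups, each taking one of three levels (parent value,
   neighbour value, midpoint), combined per the L9(3⁴) orthogonal array; the
   best of the nine candidates replaces the parent only if strictly better.
   **Gaussian mutation** (probability `p_m` = 0.1 per agent): componentwise
   `N(0, 0.1²)` perturbation, clipped, accepted only on improvement. Elitist
   acceptance in both operators keeps the best-energy trace monotone.
4. **Self-learning** on the generation best: coordinatewise golden-section
   line search in random coordinate order, each coordinate searched first
   over the full `[-1, 1]` range (tolerance 1e-3, ≤ 20 evaluations) and then
   over a narrow ±0.02 window around its current value, which sharpens the
   bracket to ~1e-5 and lets noise-free runs actually reach the convergence
   target instead of plateauing at the coarse-search floor. After the sweep,
   one extra golden-section search along the sweep's net displacement
   direction (a Powell-style acceleration) follows narrow valleys that
   axis-aligned moves traverse only by slow zigzagging — this step is what
   makes weight recovery reliable on instances whose design matrix has
   strongly correlated columns. Every candidate is kept only on strict
   improvement.

Every energy evaluation is counted (batched evaluations count one per row; a
batch that would overrun the budget is refused, so the counter can never
exceed it). A run stops at whichever comes first:

* **budget** — per-node cap `total_budget // N` with `total_budget` default
  1.5×10⁶, so a whole training run respects the global budget;
* **convergence** — best error ≤ `target_error` (default 1e-10), i.e. the
  noise-free problem is solved;
* **stagnation** — `stagnation_patience` (50) generations without a material
  improvement. "Material" means a relative best-energy improvement of at
  least `min_rel_improvement` (1e-3); the all-time best still tracks *every*
  strict improvement (the trace stays monotone), but float-level creep no
  longer keeps a finished run alive.

Per-node RNG streams are derived from `(root seed, node index)` only, so
results are bit-reproducible, independent of node execution order, and
identical between serial and `n_jobs`-parallel fits.

A **monolithic baseline** applies the identical engine to the flattened `N²`
genome (whole-matrix data error as energy). It exists for budget-matched
comparison with the decomposed trainer, not as a tuned competitor; its
self-learning pass is capped at 50 random coordinates per generation so that
a single generation cannot consume the whole budget.

## Synthetic benchmark generator

The generator's defaults are the study conditions, not tuning knobs. Step
one draws structure: exactly `E = round(density·N²)` ordered pairs (diagonal
included) chosen uniformly without replacement, each weighted `U(-1, 1)`.
Relations with `|w| < 0.05` are conventionally negligible, so each edge
weight is re-drawn until `|w| ≥ 0.05`, keeping the edge count exactly `E`; a
`strict_prune` mode zeroes sub-threshold draws instead (density shrinks
slightly). Rounding of `density·N²` is half-up and recorded in the manifest.
Step two draws each sequence's initial state from `U(0,1)^N` and free-runs
the model — the data are noise-free, so the true matrix achieves
`Data_Error = 0` exactly (asserted in tests). One root seed spawns three
independent sub-streams (positions, weights, initial states). The three
standard data regimes are `(Ns, Nt) ∈ {(1,20), (5,4), (40,10)}`, and the
benchmark grid is `N ∈ {5,10,20,40,100,200,300,500} × density ∈ {20%,40%}`.

What the generator does *not* emulate: measurement noise, stochastic
dynamics, unobserved regulators, non-logistic response — i.e. passing the
synthetic benchmarks demonstrates correct and efficient optimisation of the
stated objective, not robustness to the pathologies of real expression data.
The DREAM4 path (noisy simulated biology) is the harder case: there the
objective is fit quality only, and weight identifiability is limited (many
matrices fit 19 transitions of 100 genes equally well).

## Metrics

* `Data_Error` — as above; also per node.
* `Model_Error = (1/N²) Σ |w_ij − ŵ_ij|` — needs the ground truth; symmetric.
* `SS mean` — both matrices are binarised at `|w| > threshold` (strict;
  default 0.05) over all `N²` ordered pairs including the diagonal; with
  positive = edge present, sensitivity = TP/(TP+FN), specificity =
  TN/(TN+FP), SS mean their harmonic mean. An empty class makes its rate 0
  (never NaN) and SS mean 0 when either rate is 0 — this also produces the
  expected SS mean = 0 once the threshold exceeds every weight magnitude.
  The harmonic mean is invariant under swapping which class is called
  positive, so the value is robust to the opposite labelling convention
  found in parts of the FCM literature.
* `threshold_sweep` — tidy table of all three metrics over thresholds 0 to 1
  in steps of 0.05 (21 points); the two error metrics are
  threshold-independent and constant across rows by construction.

## Numerical and design choices

* Strict `>` at the binarisation boundary (`|w| = threshold` → no edge).
* Competition "defeats" uses strict `>`: an agent tied with `Max` is
  replaced.
* Learned weights below 0.05 are *not* zeroed in saved matrices;
  binarisation happens only inside the metrics, preserving `Model_Error`
  fidelity.
* Engine parameter values (`Lsize`, `p_o`, `p_c`, `p_m`, mutation σ, the
  L9(3⁴) crossover layout, golden-section self-learning) are this package's
  choices where the method family leaves them open; all are exposed in
  `EngineParams` and recorded in run manifests.
* DREAM4 rescaling: per-gene min-max over the retained (last 11 of 21) rows
  of all series jointly; the scaling is recorded on the returned object. A
  gene constant over the retained window is parked at 0.5 with a warning.
  All perturbation series train jointly as one multi-sequence problem.
* Degenerate inputs: sequences shorter than 2 points are rejected for
  training; genome dimensions ≤ 3 never use segment reversal; a 2×2 lattice
  keeps all four (coinciding) neighbour slots so sampling stays uniform.

## Problem sizes used in tests and the acceptance script

Small-map recovery uses the full stated design (5 nodes × 2 densities × 3
scenarios × 10 seeds); weight recovery uses one 10-node (40,10) run; budget
accounting uses one 100-node (1,20) run; the decomposed-vs-monolithic
comparison uses 40 nodes, 5 seeds, 10⁵ evaluations per algorithm. The
original 300/500-node, 10-repeat tables are deliberately not reproduced at
full scale; the 40-node comparison preserves their direction (decomposed
strictly better under equal budget).

## Known limitations

* The per-node objective is non-convex; convergence to the global optimum is
  not guaranteed, though on noise-free identifiable instances the
  accelerated coordinate-descent self-learning routinely reaches the 1e-10
  convergence target (and ≈ 1e-6 or better on the hardest single-sequence
  regimes).
* With few transitions and many nodes (e.g. one 20-point sequence, 100
  nodes) the weights are under-determined: data error goes to ~0 while the
  learned matrix can be far from the truth. This is a property of the
  problem, not the optimiser.
* Free-running simulation error compounds; all training and reported errors
  are one-step-ahead under teacher forcing.
* The monolithic baseline is intentionally plain; comparisons against it
  bound the benefit of decomposition only, not the state of the art.
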