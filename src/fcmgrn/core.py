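"""Fuzzy cognitive map (FCM) data model and forward dynamics.

An FCM is a directed, signed, weighted graph over ``N`` concept nodes (here:
genes) whose activation levels live in the unit interval.  The state of the
map at time ``t`` is a vector ``C^t in [0,1]^N`` and evolves in discrete time
through a logistic squashing of the weighted sum of incoming activations::

    C_i^{t+1} = g( sum_j  w_ji * C_j^t ),      g(x) = 1 / (1 + exp(-lam * x))

Weights are signed strengths in ``[-1, 1]``; ``w[j, i]`` is the influence of
source node ``j`` on target node ``i`` (an excitatory edge when positive,
inhibitory when negative, absent when zero).  Node ``i``'s incoming weights
are therefore the ``i``-th *column* of the matrix.  Published FCM matrices use
both orientations, so the readers/writers in :mod:`fcmgrn.io` expose a
``transpose`` flag.

Learning an ``N``-node map factorises exactly into ``N`` independent per-node
problems because one-step-ahead prediction of node ``i`` under teacher forcing
(driving the map with *observed* states) depends only on column ``i``.  The
:class:`SubMapProblem` type captures one such per-node problem; ``decompose``
and ``assemble`` convert between a full matrix and its per-node columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "DEFAULT_LAMBDA",
    "WeightMatrix",
    "ResponseSequence",
    "SequenceSet",
    "SubMapProblem",
    "squash",
    "step",
    "simulate",
    "predict_teacher_forced",
    "decompose",
    "assemble",
]

DEFAULT_LAMBDA = 5.0

_SOURCES = ("observed", "simulated", "predicted")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class WeightMatrix:
    """Square matrix of signed causal strengths, ``weights[j, i] = j -> i``.

    Entries are dimensionless and constrained to ``[-1, 1]``.  Self-loops
    (diagonal entries) are legitimate edges.
    """

    weights: np.ndarray
    node_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = _as_float_array(self.weights, "weights")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("weight matrix needs at least one node")
        if np.any(np.abs(w) > 1.0):
            raise ValueError("weights must lie in [-1, 1]")
        object.__setattr__(self, "weights", w)
        if self.node_names is not None:
            names = tuple(str(n) for n in self.node_names)
            if len(names) != w.shape[0]:
                raise ValueError("node_names length must match matrix size")
            object.__setattr__(self, "node_names", names)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def incoming(self, node_index: int) -> np.ndarray:
        """Incoming-weight vector of 1-based node ``node_index`` (a column)."""
        if not 1 <= node_index <= self.n_nodes:
            raise ValueError(f"node_index {node_index} outside [1, {self.n_nodes}]")
        return self.weights[:, node_index - 1].copy()

    def __eq__(self, other) -> bool:  # value semantics for tests
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        return (
            self.weights.shape == other.weights.shape
            and bool(np.array_equal(self.weights, other.weights))
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ResponseSequence:
    """One trajectory: ``states[t]`` is the activation vector at time ``t``.

    ``source`` records provenance: ``observed`` (training data), ``simulated``
    (free-running model output) or ``predicted`` (one-step-ahead output).
    Training requires at least two rows (one ``(t, t+1)`` transition).
    """

    states: np.ndarray
    source: str = "observed"

    def __post_init__(self) -> None:
        s = _as_float_array(self.states, "states")
        if s.ndim != 2:
            raise ValueError("states must be a 2-D (time x node) array")
        if s.shape[0] < 1:
            raise ValueError("a sequence needs at least one time point")
        if np.any(s < 0.0) or np.any(s > 1.0):
            raise ValueError("state values must lie in [0, 1]")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        object.__setattr__(self, "states", s)

    @property
    def n_time(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class SequenceSet:
    """A bundle of response sequences over the same node set.

    Sequence lengths may differ; the node count may not.
    """

    sequences: tuple[ResponseSequence, ...]

    def __post_init__(self) -> None:
        seqs = tuple(
            s if isinstance(s, ResponseSequence) else ResponseSequence(s)
            for s in self.sequences
        )
        if len(seqs) < 1:
            raise ValueError("SequenceSet needs at least one sequence")
        n = seqs[0].n_nodes
        if any(s.n_nodes != n for s in seqs):
            raise ValueError("all sequences must share the same node count")
        object.__setattr__(self, "sequences", seqs)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_nodes(self) -> int:
        return self.sequences[0].n_nodes

    @property
    def n_transitions(self) -> int:
        return sum(s.n_time - 1 for s in self.sequences)

    def transitions(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack all ``(t, t+1)`` pairs: returns ``(X, Y)``.

        ``X[k]`` is the state preceding transition ``k`` and ``Y[k]`` the state
        following it, concatenated across sequences in order.  Every sequence
        must contribute at least one transition.
        """
        if any(s.n_time < 2 for s in self.sequences):
            raise ValueError("every sequence needs >= 2 time points for training")
        X = np.vstack([s.states[:-1] for s in self.sequences])
        Y = np.vstack([s.states[1:] for s in self.sequences])
        return X, Y


@dataclass(frozen=True)
class SubMapProblem:
    """The learning problem for one node: its incoming-weight column + data.

    ``node_index`` is 1-based; ``incoming_weights`` corresponds to column
    ``node_index`` of a full :class:`WeightMatrix` and is the candidate (or
    learned) solution.  ``data`` carries the teacher-forcing sequences; it may
    be ``None`` for purely structural uses.
    """

    node_index: int
    incoming_weights: np.ndarray
    data: SequenceSet | None = None

    def __post_init__(self) -> None:
        w = _as_float_array(self.incoming_weights, "incoming_weights")
        if w.ndim != 1:
            raise ValueError("incoming_weights must be a 1-D vector")
        if np.any(np.abs(w) > 1.0):
            raise ValueError("incoming weights must lie in [-1, 1]")
        if not 1 <= self.node_index <= w.shape[0]:
            raise ValueError(
                f"node_index {self.node_index} outside [1, {w.shape[0]}]"
            )
        if self.data is not None and self.data.n_nodes != w.shape[0]:
            raise ValueError("data node count must match incoming_weights length")
        object.__setattr__(self, "incoming_weights", w)

    @property
    def n_nodes(self) -> int:
        return self.incoming_weights.shape[0]


def squash(x, lam: float = DEFAULT_LAMBDA):
    """Logistic transfer ``g(x) = 1 / (1 + exp(-lam * x))``.

    Strictly increasing in ``x`` with range ``(0, 1)``; ``lam`` controls the
    slope (default 5).  Accepts scalars or arrays.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lam must be a positive finite number")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    out = expit(lam * arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def step(model: WeightMatrix, state, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """One synchronous update: ``out_i = g(sum_j w_ji * state_j)``."""
    s = _as_float_array(state, "state")
    if s.ndim != 1 or s.shape[0] != model.n_nodes:
        raise ValueError(
            f"state length {s.shape} does not match model with {model.n_nodes} nodes"
        )
    return squash(s @ model.weights, lam)


def simulate(
    model: WeightMatrix,
    initial,
    n_time: int,
    lam: float = DEFAULT_LAMBDA,
) -> ResponseSequence:
    """Free-run the map for ``n_time`` points starting from ``initial``.

    Row 0 of the result is ``initial`` itself; each later row is one ``step``
    applied to its predecessor.  All rows after the first lie strictly inside
    ``(0, 1)`` by the sigmoid range.
    """
    if n_time < 1:
        raise ValueError("n_time must be >= 1")
    init = _as_float_array(initial, "initial")
    if init.ndim != 1 or init.shape[0] != model.n_nodes:
        raise ValueError("initial state length must match model node count")
    states = np.empty((n_time, model.n_nodes))
    states[0] = init
    for t in range(1, n_time):
        states[t] = step(model, states[t - 1], lam)
    return ResponseSequence(states=states, source="simulated")


def predict_teacher_forced(
    problem: SubMapProblem, lam: float = DEFAULT_LAMBDA
) -> list[np.ndarray]:
    """One-step-ahead predictions for one node, driven by observed states.

    For each sequence ``s`` the prediction at position ``t`` (0-based, length
    ``Nt - 1``) is ``g(sum_j w_j * C_j^t(s))`` — i.e. the predicted value of
    the node at time ``t + 1`` given the *observed* state at time ``t``.
    Predictions depend only on this node's incoming column, which is what
    makes the per-node decomposition exact.
    """
    if problem.data is None:
        raise ValueError("SubMapProblem carries no data")
    w = problem.incoming_weights
    out = []
    for seq in problem.data.sequences:
        if seq.n_time < 2:
            raise ValueError("every sequence needs >= 2 time points")
        out.append(squash(seq.states[:-1] @ w, lam))
    return out


def decompose(
    model: WeightMatrix, data: SequenceSet | None = None
) -> list[SubMapProblem]:
    """Split an N-node map into its N per-node sub-problems (matrix columns)."""
    return [
        SubMapProblem(node_index=i, incoming_weights=model.weights[:, i - 1], data=data)
        for i in range(1, model.n_nodes + 1)
    ]


def assemble(submaps: Iterable[SubMapProblem]) -> WeightMatrix:
    """Inverse of :func:`decompose`: stack per-node columns into a matrix.

    Requires exactly one sub-problem per node index ``1..N``, each of length
    ``N``; the input order is irrelevant.
    """
    subs = list(submaps)
    if not subs:
        raise ValueError("no submaps given")
    n = subs[0].n_nodes
    if any(s.n_nodes != n for s in subs):
        raise ValueError("all submaps must have the same length")
    indices = sorted(s.node_index for s in subs)
    if indices != list(range(1, n + 1)):
        raise ValueError(
            f"need exactly one submap per node 1..{n}, got indices {indices}"
        )
    w = np.empty((n, n))
    for s in subs:
        w[:, s.node_index - 1] = s.incoming_weights
    return WeightMatrix(weights=w)
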