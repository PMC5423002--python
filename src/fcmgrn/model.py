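"""Model/Results interface for FCM learning.

:class:`FCM` is constructed from a set of response sequences and holds the
data plus the transfer-function slope; :meth:`FCM.fit` runs the decomposed
lattice optimiser on every node and returns an :class:`FCMResults` carrying
the learned weight matrix, per-node optimisation diagnostics, the training
error and the evaluation accounting.  Simulation, evaluation against a known
ground truth, threshold sweeps and a text summary hang off the results
object.

Because the per-node problems are independent and each derives its RNG
stream from (root seed, node index), fitting is embarrassingly parallel:
``fit(n_jobs=...)`` uses joblib and produces results identical to the serial
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import metrics as _metrics
from .core import (
    DEFAULT_LAMBDA,
    ResponseSequence,
    SequenceSet,
    SubMapProblem,
    WeightMatrix,
    assemble,
    simulate,
)
from .dmaga import EngineParams, OptimizeResult, optimize_submap

__all__ = ["FCM", "FCMResults"]


class FCM:
    """Fuzzy-cognitive-map model of a gene regulatory network.

    Parameters
    ----------
    data
        Training trajectories: a :class:`SequenceSet`, or anything accepted
        by :meth:`from_arrays` (a single 2-D array or a list of them).
    lam
        Slope of the logistic transfer function (default 5).
    """

    def __init__(self, data, lam: float = DEFAULT_LAMBDA):
        if not isinstance(data, SequenceSet):
            data = self._coerce(data)
        if any(s.n_time < 2 for s in data.sequences):
            raise ValueError("training sequences need at least 2 time points")
        if data.n_nodes < 2:
            raise ValueError("training needs at least 2 nodes")
        self.data = data
        self.lam = float(lam)

    @staticmethod
    def _coerce(data) -> SequenceSet:
        arr = np.asarray(data, dtype=float) if not isinstance(data, (list, tuple)) else None
        if arr is not None and arr.ndim == 2:
            return SequenceSet(sequences=(ResponseSequence(states=arr),))
        return SequenceSet(
            sequences=tuple(ResponseSequence(states=np.asarray(a, dtype=float)) for a in data)
        )

    @classmethod
    def from_arrays(cls, arrays, lam: float = DEFAULT_LAMBDA) -> "FCM":
        """Build from one 2-D (time x node) array or a list of them."""
        return cls(cls._coerce(arrays), lam=lam)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sequence_col: str = "sequence_id",
        time_col: str = "time_index",
        lam: float = DEFAULT_LAMBDA,
    ) -> "FCM":
        """Build from a long-form frame with one row per (sequence, time)."""
        if sequence_col not in df.columns or time_col not in df.columns:
            raise ValueError(f"frame must contain '{sequence_col}' and '{time_col}'")
        node_cols = [c for c in df.columns if c not in (sequence_col, time_col)]
        seqs = []
        for _, group in df.groupby(sequence_col, sort=True):
            states = group.sort_values(time_col)[node_cols].to_numpy(dtype=float)
            seqs.append(ResponseSequence(states=states))
        return cls(SequenceSet(sequences=tuple(seqs)), lam=lam)

    @property
    def n_nodes(self) -> int:
        return self.data.n_nodes

    def fit(
        self,
        params: EngineParams | None = None,
        n_jobs: int = 1,
        **overrides,
    ) -> "FCMResults":
        """Learn the weight matrix by optimising each node independently.

        ``overrides`` are applied on top of ``params`` (or the defaults),
        e.g. ``fit(seed=3, total_budget=50_000)``.  With ``n_jobs != 1`` the
        per-node problems run in parallel; results are identical to the
        serial run because each node's RNG stream depends only on the root
        seed and the node index.
        """
        if params is None:
            params = EngineParams()
        if overrides:
            params = replace(params, **overrides)
        if params.lam != self.lam:
            params = replace(params, lam=self.lam)

        def _one(node: int) -> OptimizeResult:
            problem = SubMapProblem(
                node_index=node,
                incoming_weights=np.zeros(self.n_nodes),
                data=self.data,
            )
            return optimize_submap(problem, params)

        nodes = range(1, self.n_nodes + 1)
        if n_jobs == 1:
            node_results = [_one(i) for i in nodes]
        else:
            node_results = Parallel(n_jobs=n_jobs)(delayed(_one)(i) for i in nodes)

        learned = assemble(
            SubMapProblem(node_index=i, incoming_weights=r.best_genome)
            for i, r in zip(nodes, node_results)
        )
        return FCMResults(
            model=self,
            params=params,
            weights=learned,
            node_results=tuple(node_results),
        )


@dataclass(frozen=True)
class FCMResults:
    """Outcome of one training run (the run record).

    Carries the learned matrix, the per-node optimiser results, and derived
    diagnostics.  ``data_error`` recomputes the whole-map training error from
    the assembled matrix; by the exact per-node decomposition it equals the
    mean of the per-node best errors up to float round-off.
    """

    model: FCM
    params: EngineParams
    weights: WeightMatrix
    node_results: tuple[OptimizeResult, ...]

    @property
    def n_nodes(self) -> int:
        return self.weights.n_nodes

    @property
    def data_error(self) -> float:
        return _metrics.data_error(self.weights, self.model.data, self.model.lam)

    @property
    def node_errors(self) -> np.ndarray:
        return np.array([r.best_error for r in self.node_results])

    @property
    def total_evaluations(self) -> int:
        return int(sum(r.evaluations_used for r in self.node_results))

    def simulate(self, initial, n_time: int) -> ResponseSequence:
        """Free-run the learned map from ``initial`` for ``n_time`` points."""
        return simulate(self.weights, initial, n_time, self.model.lam)

    def evaluate(
        self,
        truth: WeightMatrix | None = None,
        threshold: float = _metrics.DEFAULT_THRESHOLD,
    ) -> _metrics.EvaluationReport:
        """Metric report; structural metrics require a ground-truth matrix."""
        de = self.data_error
        if truth is None:
            return _metrics.EvaluationReport(data_error=de, threshold=threshold)
        if truth.n_nodes != self.n_nodes:
            raise ValueError("ground truth size does not match learned matrix")
        counts = _metrics.confusion(
            _metrics.binarize(truth, threshold),
            _metrics.binarize(self.weights, threshold),
        )
        return _metrics.EvaluationReport(
            data_error=de,
            threshold=threshold,
            model_error=_metrics.model_error(truth, self.weights),
            sensitivity=_metrics.sensitivity(counts),
            specificity=_metrics.specificity(counts),
            ss_mean=_metrics.ss_mean(counts),
        )

    def threshold_sweep(
        self, truth: WeightMatrix, thresholds: Sequence[float] | None = None
    ) -> pd.DataFrame:
        return _metrics.threshold_sweep(
            truth, self.weights, self.model.data, thresholds, self.model.lam
        )

    def manifest(self) -> dict:
        """Flat run record suitable for YAML serialisation."""
        p = self.params
        return {
            "n_nodes": self.n_nodes,
            "n_sequences": self.model.data.n_sequences,
            "lam": self.model.lam,
            "seed": p.seed,
            "lsize": p.lsize,
            "p_o": p.p_o,
            "p_c": p.p_c,
            "p_m": p.p_m,
            "total_budget": p.total_budget,
            "eval_budget": p.eval_budget,
            "stagnation_patience": p.stagnation_patience,
            "target_error": p.target_error,
            "data_error": float(self.data_error),
            "total_evaluations": self.total_evaluations,
            "node_evaluations": [int(r.evaluations_used) for r in self.node_results],
            "node_errors": [float(e) for e in self.node_errors],
            "node_generations": [int(r.generations) for r in self.node_results],
        }

    def summary(self) -> str:
        """Human-readable run summary."""
        data = self.model.data
        lines = [
            "FCM training results (decomposed multi-agent GA)",
            "=" * 48,
            f"nodes:               {self.n_nodes}",
            f"sequences:           {data.n_sequences}"
            f"  (transitions: {data.n_transitions})",
            f"lambda:              {self.model.lam:g}",
            f"seed:                {self.params.seed}",
            f"data_error:          {self.data_error:.6g}",
            f"total evaluations:   {self.total_evaluations}",
            f"generations (sum):   {sum(r.generations for r in self.node_results)}",
            f"worst node error:    {self.node_errors.max():.6g}",
            f"best node error:     {self.node_errors.min():.6g}",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot per-node best-energy traces (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, r in enumerate(self.node_results, start=1):
            ax.plot(-r.trace, label=f"node {i}")
        ax.set_xlabel("generation")
        ax.set_ylabel("best node data error")
        ax.set_yscale("log")
        if self.n_nodes <= 10:
            ax.legend(fontsize="small")
        return ax
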