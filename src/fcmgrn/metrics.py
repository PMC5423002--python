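"""Evaluation metrics for learned fuzzy cognitive maps.

Three complementary views of reconstruction quality:

* ``data_error`` — mean squared one-step-ahead prediction error under teacher
  forcing, averaged over nodes, sequences and transitions.  This is the
  training objective; it decomposes exactly into the mean of per-node errors
  (``node_data_error``), which is what licenses per-node optimisation.
* ``model_error`` — mean absolute entrywise difference between a learned and
  a ground-truth weight matrix (requires the truth; symmetric).
* ``ss_mean`` — harmonic mean of sensitivity and specificity of binarised
  edge prediction.  Both matrices are thresholded at ``|w| > threshold``
  (strict; default 0.05 — weaker relations are conventionally treated as
  absent in FCM practice) and every ordered node pair, diagonal included, is
  classified as edge-present (positive) or edge-absent (negative).

Zero-denominator convention: an empty class makes its rate 0 (not NaN), and
``ss_mean`` is 0 whenever either rate is 0.  The harmonic mean is symmetric
under swapping which class is called positive, so this choice never changes
the reported ``ss_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_LAMBDA,
    SequenceSet,
    SubMapProblem,
    WeightMatrix,
    squash,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "ConfusionCounts",
    "EvaluationReport",
    "node_data_error",
    "data_error",
    "model_error",
    "binarize",
    "confusion",
    "sensitivity",
    "specificity",
    "ss_mean",
    "threshold_sweep",
]

DEFAULT_THRESHOLD = 0.05


def node_data_error(problem: SubMapProblem, lam: float = DEFAULT_LAMBDA) -> float:
    """Mean squared one-step-ahead residual for one node.

    Averages ``(C_i^{t+1}(s) - Chat_i^{t+1}(s))^2`` over all ``Ns * (Nt - 1)``
    teacher-forced transitions.  Zero iff predictions match observations
    exactly.
    """
    if problem.data is None:
        raise ValueError("SubMapProblem carries no data")
    X, Y = problem.data.transitions()
    preds = squash(X @ problem.incoming_weights, lam)
    resid = Y[:, problem.node_index - 1] - preds
    return float(np.mean(resid**2))


def data_error(
    model: WeightMatrix, data: SequenceSet, lam: float = DEFAULT_LAMBDA
) -> float:
    """Whole-map mean squared one-step-ahead error (the training objective).

    Normalised by ``N * Ns * (Nt - 1)`` terms; equal to the mean of the
    per-node errors up to float associativity.
    """
    if data.n_nodes != model.n_nodes:
        raise ValueError("data node count does not match model")
    X, Y = data.transitions()
    preds = squash(X @ model.weights, lam)
    return float(np.mean((Y - preds) ** 2))


def model_error(target: WeightMatrix, learned: WeightMatrix) -> float:
    """Mean absolute entrywise weight difference, ``(1/N^2) sum |w - w_hat|``."""
    if target.n_nodes != learned.n_nodes:
        raise ValueError("matrices differ in size")
    return float(np.mean(np.abs(target.weights - learned.weights)))


def binarize(model: WeightMatrix, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Edge-presence matrix: 1 where ``|w| > threshold`` (strict), else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return (np.abs(model.weights) > threshold).astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-classification tallies over all N^2 ordered node pairs.

    Positive = edge present after binarisation.  ``n_tp`` counts pairs that
    carry an edge in both matrices, ``n_tn`` pairs with an edge in neither,
    ``n_fp`` spurious learned edges, ``n_fn`` missed true edges.
    """

    n_tp: int
    n_fn: int
    n_tn: int
    n_fp: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_fn", "n_tn", "n_fp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fn + self.n_tn + self.n_fp


def confusion(target_bin: np.ndarray, learned_bin: np.ndarray) -> ConfusionCounts:
    """Tally TP/FN/TN/FP between two binary edge matrices of equal shape."""
    t = np.asarray(target_bin)
    l = np.asarray(learned_bin)
    if t.shape != l.shape:
        raise ValueError("binary matrices differ in shape")
    for name, m in (("target", t), ("learned", l)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} matrix is not binary")
    return ConfusionCounts(
        n_tp=int(np.sum((t == 1) & (l == 1))),
        n_fn=int(np.sum((t == 1) & (l == 0))),
        n_tn=int(np.sum((t == 0) & (l == 0))),
        n_fp=int(np.sum((t == 0) & (l == 1))),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """``TP / (TP + FN)``; 0 when no true edges exist."""
    denom = counts.n_tp + counts.n_fn
    return counts.n_tp / denom if denom else 0.0


def specificity(counts: ConfusionCounts) -> float:
    """``TN / (TN + FP)``; 0 when no true non-edges exist."""
    denom = counts.n_tn + counts.n_fp
    return counts.n_tn / denom if denom else 0.0


def ss_mean(counts: ConfusionCounts) -> float:
    """Harmonic mean of sensitivity and specificity; 0 if either rate is 0."""
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    sens = sensitivity(counts)
    spec = specificity(counts)
    if sens + spec == 0.0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


@dataclass(frozen=True)
class EvaluationReport:
    """Flat bundle of the evaluation metrics at one binarisation threshold.

    ``model_error``, ``sensitivity``, ``specificity`` and ``ss_mean`` are
    ``None`` when no ground-truth matrix was supplied.
    """

    data_error: float
    threshold: float = DEFAULT_THRESHOLD
    model_error: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ss_mean: float | None = None

    def to_text(self) -> str:
        lines = [f"data_error\t{self.data_error:.6g}", f"threshold\t{self.threshold:g}"]
        for key in ("model_error", "sensitivity", "specificity", "ss_mean"):
            v = getattr(self, key)
            if v is not None:
                lines.append(f"{key}\t{v:.6g}")
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "data_error": self.data_error,
                    "model_error": self.model_error,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "ss_mean": self.ss_mean,
                    "threshold": self.threshold,
                }
            ]
        )


def threshold_sweep(
    target: WeightMatrix,
    learned: WeightMatrix,
    data: SequenceSet,
    thresholds: Sequence[float] | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> pd.DataFrame:
    """Evaluate ``ss_mean`` over a grid of binarisation thresholds.

    Default grid: 0 to 1 in steps of 0.05 (21 points).  ``data_error`` and
    ``model_error`` do not depend on the threshold and are repeated in every
    row so the output is a tidy, self-contained table.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("threshold list is empty")
    if any(t < 0.0 or t > 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    de = data_error(learned, data, lam)
    me = model_error(target, learned)
    rows = []
    for thr in thresholds:
        counts = confusion(binarize(target, thr), binarize(learned, thr))
        rows.append(
            {
                "threshold": thr,
                "data_error": de,
                "model_error": me,
                "ss_mean": ss_mean(counts),
            }
        )
    return pd.DataFrame(rows)
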