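"""Functional end-to-end wrappers around the Model/Results interface.

These are thin conveniences for script use; the richer surface lives on
:class:`fcmgrn.model.FCM` and :class:`fcmgrn.model.FCMResults`.
"""

from __future__ import annotations

from pathlib import Path

from .core import SequenceSet, WeightMatrix
from .dmaga import EngineParams
from .io import Dream4Series, load_dream4
from .metrics import (
    DEFAULT_THRESHOLD,
    EvaluationReport,
    binarize,
    confusion,
    data_error,
    model_error,
    sensitivity,
    specificity,
    ss_mean,
)
from .model import FCM, FCMResults

__all__ = ["train", "evaluate", "load_dream4", "train_dream4"]


def train(
    data: SequenceSet,
    params: EngineParams | None = None,
    n_jobs: int = 1,
    **overrides,
) -> FCMResults:
    """Fit an FCM to a sequence set; see :meth:`fcmgrn.model.FCM.fit`."""
    lam = overrides.get("lam", params.lam if params is not None else None)
    model = FCM(data) if lam is None else FCM(data, lam=lam)
    return model.fit(params=params, n_jobs=n_jobs, **overrides)


def evaluate(
    learned: WeightMatrix,
    truth: WeightMatrix | None,
    data: SequenceSet,
    threshold: float = DEFAULT_THRESHOLD,
    lam: float | None = None,
) -> EvaluationReport:
    """Metric report for an already-learned matrix.

    ``data_error`` is always computed; ``model_error`` and the structural
    classification metrics require the ground truth.
    """
    if data.n_nodes != learned.n_nodes:
        raise ValueError("data node count does not match learned matrix")
    kwargs = {} if lam is None else {"lam": lam}
    de = data_error(learned, data, **kwargs)
    if truth is None:
        return EvaluationReport(data_error=de, threshold=threshold)
    if truth.n_nodes != learned.n_nodes:
        raise ValueError("ground truth size does not match learned matrix")
    counts = confusion(binarize(truth, threshold), binarize(learned, threshold))
    return EvaluationReport(
        data_error=de,
        threshold=threshold,
        model_error=model_error(truth, learned),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        ss_mean=ss_mean(counts),
    )


def train_dream4(
    path: str | Path,
    params: EngineParams | None = None,
    n_jobs: int = 1,
    **overrides,
) -> tuple[Dream4Series, FCMResults]:
    """Load a DREAM4 time-series file and train on all series jointly.

    All perturbation series enter one multi-sequence training problem (the
    per-node objective averages over every series), matching the
    multi-sequence form of the data-error objective.
    """
    series = load_dream4(path)
    results = train(series.to_sequence_set(), params=params, n_jobs=n_jobs, **overrides)
    return series, results
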