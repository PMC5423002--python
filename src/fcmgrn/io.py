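"""File formats: weight matrices, response sequences, DREAM4 time series.

Weight matrices are square numeric TSV/CSV, optionally with a header row (and
matching index column) of node names, written at 17 significant digits so
round trips are exact.  The on-disk orientation matches the in-memory one —
``cell (j, i) = edge j -> i`` — and a ``transpose`` flag is available because
published FCM matrices use both conventions.

Sequence sets are long-form CSV with columns ``sequence_id, time_index,
node_1..node_N`` (one row per time point), plus a wide TSV alternative in the
DREAM time-series style: a ``Time`` column, gene-name columns, and sequences
stacked as consecutive blocks separated by the time index resetting.

The DREAM4 loader handles the in-silico challenge layout: tab-delimited,
header row of gene names, one block of 21 time points per perturbation
series.  The perturbation is lifted at the 11th time point, so only the last
11 rows of each block — the relaxation back to the wild type — are retained.
Expression values are min-max scaled per gene into [0, 1] over the retained
rows, and the scaling is recorded for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ResponseSequence, SequenceSet, WeightMatrix

__all__ = [
    "write_weight_matrix",
    "read_weight_matrix",
    "write_sequences",
    "read_sequences",
    "write_sequences_wide",
    "read_sequences_wide",
    "Dream4Series",
    "load_dream4",
]

_FMT = "%.17g"

DREAM4_BLOCK = 21
DREAM4_KEEP = 11


def write_weight_matrix(
    path: str | Path,
    model: WeightMatrix,
    sep: str = "\t",
    transpose: bool = False,
) -> None:
    """Write a weight matrix; exact round trip at 17 significant digits."""
    w = model.weights.T if transpose else model.weights
    if model.node_names is not None:
        df = pd.DataFrame(w, index=model.node_names, columns=model.node_names)
        df.to_csv(path, sep=sep, float_format=_FMT)
    else:
        np.savetxt(path, w, fmt=_FMT, delimiter=sep)


def read_weight_matrix(
    path: str | Path, sep: str = "\t", transpose: bool = False
) -> WeightMatrix:
    """Read a square numeric matrix; a non-numeric first row is a name header.

    When a header is present, a matching leading index column of names is
    accepted too.  ``transpose`` flips the on-disk orientation on read.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split(sep)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    if has_header:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        names = tuple(str(c) for c in df.columns)
        w = df.to_numpy(dtype=float)
    else:
        names = None
        w = np.loadtxt(path, delimiter=sep, ndmin=2)
    if transpose:
        w = w.T
    return WeightMatrix(weights=w, node_names=names)


def _node_columns(n: int) -> list[str]:
    return [f"node_{i}" for i in range(1, n + 1)]


def write_sequences(path: str | Path, data: SequenceSet) -> None:
    """Long-form CSV: one row per (sequence, time point)."""
    frames = []
    for s, seq in enumerate(data.sequences, start=1):
        df = pd.DataFrame(seq.states, columns=_node_columns(data.n_nodes))
        df.insert(0, "time_index", np.arange(1, seq.n_time + 1))
        df.insert(0, "sequence_id", s)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format=_FMT)


def read_sequences(path: str | Path, source: str = "observed") -> SequenceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sequence_id", "time_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"sequence CSV must contain columns {sorted(required)}")
    node_cols = [c for c in df.columns if c not in required]
    seqs = []
    for _, group in df.groupby("sequence_id", sort=True):
        states = group.sort_values("time_index")[node_cols].to_numpy(dtype=float)
        seqs.append(ResponseSequence(states=states, source=source))
    return SequenceSet(sequences=tuple(seqs))


def write_sequences_wide(path: str | Path, data: SequenceSet) -> None:
    """Wide TSV: Time column + node columns, sequences as stacked blocks."""
    frames = []
    for seq in data.sequences:
        df = pd.DataFrame(seq.states, columns=_node_columns(data.n_nodes))
        df.insert(0, "Time", np.arange(1, seq.n_time + 1))
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_sequences_wide(path: str | Path, source: str = "observed") -> SequenceSet:
    """Read stacked wide TSV; a new block starts whenever Time resets."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    time = df.iloc[:, 0].to_numpy()
    starts = [0] + [i for i in range(1, len(time)) if time[i] <= time[i - 1]]
    bounds = starts + [len(time)]
    seqs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        states = df.iloc[lo:hi, 1:].to_numpy(dtype=float)
        seqs.append(ResponseSequence(states=states, source=source))
    return SequenceSet(sequences=tuple(seqs))


@dataclass(frozen=True)
class Dream4Series:
    """Parsed DREAM4 time-series file after truncation and rescaling.

    ``series`` holds one 11-point sequence per perturbation experiment;
    ``scale_min``/``scale_max`` record the per-gene min-max used to map raw
    expression values into [0, 1].
    """

    gene_names: tuple[str, ...]
    series: tuple[ResponseSequence, ...]
    scale_min: np.ndarray
    scale_max: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(sequences=self.series)


def load_dream4(path: str | Path) -> Dream4Series:
    """Load a DREAM4 in-silico time-series file.

    Expects tab-delimited data with a header row (first column time, then one
    column per gene) and stacked blocks of exactly 21 rows, one per
    perturbation series.  Keeps the last 11 rows of each block and min-max
    scales each gene over all retained rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    genes = tuple(str(c) for c in df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    n_rows = values.shape[0]
    if n_rows == 0 or n_rows % DREAM4_BLOCK != 0:
        raise ValueError(
            f"{path.name}: {n_rows} data rows is not a multiple of "
            f"{DREAM4_BLOCK}; block {n_rows // DREAM4_BLOCK + 1} is truncated"
        )
    n_series = n_rows // DREAM4_BLOCK
    kept = [
        values[b * DREAM4_BLOCK + (DREAM4_BLOCK - DREAM4_KEEP) : (b + 1) * DREAM4_BLOCK]
        for b in range(n_series)
    ]
    stacked = np.vstack(kept)
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = hi - lo
    flat = span == 0  # constant gene: park it mid-range
    span = np.where(flat, 1.0, span)
    if np.any(flat):
        warnings.warn(
            f"{path.name}: {int(flat.sum())} gene(s) constant over the retained "
            "rows; their scaled values are set to 0.5",
            stacklevel=2,
        )
    series = []
    for block in kept:
        scaled = (block - lo) / span
        scaled[:, flat] = 0.5
        series.append(ResponseSequence(states=scaled, source="observed"))
    return Dream4Series(
        gene_names=genes,
        series=tuple(series),
        scale_min=lo,
        scale_max=hi,
    )
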