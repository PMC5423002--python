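"""Synthetic FCM benchmarks: sparse random maps plus noise-free trajectories.

The generator follows a two-step protocol.  Step one draws a sparse ground
truth: exactly ``E = round(density * N^2)`` of the ``N^2`` ordered node pairs
(diagonal included — self-regulation is a legitimate edge) are selected
uniformly without replacement, and each selected edge receives a weight drawn
from ``U(-1, 1)``.  Relations weaker than 0.05 in absolute value are
conventionally ignored in FCM practice, so by default each edge weight is
re-drawn until ``|w| >= 0.05``; this keeps the realised edge count exactly at
``E``.  A ``strict_prune`` mode instead zeroes sub-threshold draws, which
shrinks the realised density slightly.  Step two draws each sequence's
initial state from ``U(0, 1)^N`` and free-runs the map forward, so the
resulting data are noise-free and exactly reproducible by the simulator.

One root seed spawns three independent sub-streams (edge positions, edge
weights, initial states), so each component can be regenerated on its own.
``SCENARIOS`` lists the three standard (Ns, Nt) data regimes used throughout:
one long sequence (1, 20), a few very short ones (5, 4), and many medium ones
(40, 10).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .core import (
    DEFAULT_LAMBDA,
    ResponseSequence,
    SequenceSet,
    WeightMatrix,
    simulate,
)

__all__ = [
    "SCENARIOS",
    "GeneratorConfig",
    "Benchmark",
    "generate_fcm",
    "generate_sequences",
    "make_benchmark",
]

# (n_sequences, n_time) presets: one long, few short, many medium.
SCENARIOS: tuple[tuple[int, int], ...] = ((1, 20), (5, 4), (40, 10))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic benchmark instance."""

    n_nodes: int
    edge_density: float = 0.2
    n_sequences: int = 1
    n_time: int = 20
    lam: float = DEFAULT_LAMBDA
    prune_threshold: float = 0.05
    seed: int = 0
    strict_prune: bool = False

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.n_time < 2:
            raise ValueError("n_time must be >= 2")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0.0 <= self.prune_threshold < 1.0:
            raise ValueError("prune_threshold must lie in [0, 1)")
        if self.n_edges < 1:
            raise ValueError("edge_density * n_nodes^2 rounds to zero edges")

    @property
    def n_edges(self) -> int:
        """Target edge count: ``density * N^2`` rounded half-up."""
        return int(math.floor(self.edge_density * self.n_nodes**2 + 0.5))


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_fcm(config: GeneratorConfig) -> WeightMatrix:
    """Draw a sparse ground-truth map with exactly ``config.n_edges`` edges.

    Deterministic given ``config.seed``.  In the default mode every nonzero
    weight satisfies ``prune_threshold <= |w| <= 1``; with ``strict_prune``
    sub-threshold draws are zeroed instead (realised density may shrink).
    """
    n = config.n_nodes
    n_edges = config.n_edges
    if n_edges > n * n:
        raise ValueError("edge count exceeds N^2")
    rng_pos, rng_w, _ = _streams(config.seed)
    flat = rng_pos.choice(n * n, size=n_edges, replace=False)
    values = rng_w.uniform(-1.0, 1.0, size=n_edges)
    if config.strict_prune:
        values[np.abs(values) < config.prune_threshold] = 0.0
    else:
        # re-draw weights that fall inside the dead band (-thr, thr)
        weak = np.abs(values) < config.prune_threshold
        while np.any(weak):
            values[weak] = rng_w.uniform(-1.0, 1.0, size=int(weak.sum()))
            weak = np.abs(values) < config.prune_threshold
    w = np.zeros(n * n)
    w[flat] = values
    return WeightMatrix(weights=w.reshape(n, n))


def generate_sequences(model: WeightMatrix, config: GeneratorConfig) -> SequenceSet:
    """Free-run ``Ns`` noise-free trajectories from ``U(0,1)^N`` initial states.

    Deterministic given ``config.seed``; uses a sub-stream independent of the
    one that drew the matrix.  The returned sequences are marked ``observed``
    because they play the role of training data.
    """
    if model.n_nodes != config.n_nodes:
        raise ValueError("model size does not match config.n_nodes")
    _, _, rng_init = _streams(config.seed)
    seqs = []
    for _ in range(config.n_sequences):
        init = rng_init.uniform(0.0, 1.0, size=config.n_nodes)
        traj = simulate(model, init, config.n_time, config.lam)
        seqs.append(ResponseSequence(states=traj.states, source="observed"))
    return SequenceSet(sequences=tuple(seqs))


@dataclass(frozen=True)
class Benchmark:
    """Matched ground truth + data + the manifest that reproduces them."""

    truth: WeightMatrix
    data: SequenceSet
    manifest: dict


def make_benchmark(config: GeneratorConfig, out_dir: str | Path | None = None) -> Benchmark:
    """Generate a ground truth/data pair and optionally write it to disk.

    The manifest records every config field plus derived quantities (edge
    count, rounding rule), which is enough to regenerate the bundle
    bit-identically.  When ``out_dir`` is given, writes ``ground_truth.tsv``,
    ``sequences.csv`` and ``manifest.yaml`` there.
    """
    truth = generate_fcm(config)
    data = generate_sequences(truth, config)
    manifest = dict(asdict(config))
    manifest["n_edges"] = config.n_edges
    manifest["edge_count_rounding"] = "half-up"
    bundle = Benchmark(truth=truth, data=data, manifest=manifest)
    if out_dir is not None:
        from . import io as _io  # deferred to avoid a cycle at import time

        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            _io.write_weight_matrix(out / "ground_truth.tsv", truth)
            _io.write_sequences(out / "sequences.csv", data)
            with open(out / "manifest.yaml", "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=False)
        except OSError as exc:
            raise OSError(f"failed writing benchmark bundle to {out}: {exc}") from exc
    return bundle
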