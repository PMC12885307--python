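"""Synthetic BI-RADS-style tables with planted, label-coherent blocks.

The generator emulates the structure the rule miner is designed to exploit:
within one label class, a subset of samples shares the same score on a
subset of descriptors (a column-constant block), embedded in a categorical
background.  Block membership, pattern fidelity (``coherence``), label
noise and the benign/malignant imbalance are all controllable, so every
downstream stage — oversampling, coclustering, rule extraction, boosting —
can be tested against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .schema_io import (
    BENIGN,
    MALIGNANT,
    FeatureSchema,
    SampleTable,
    default_schema,
)

__all__ = [
    "PlantedBlock",
    "SynthConfig",
    "generate",
    "imbalanced_subset",
    "matching_rows",
    "default_config",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A column-constant pattern planted into one label class.

    ``feature_indices`` (>= 3 columns) and ``level_pattern`` define the
    pattern; ``n_rows`` (>= 5) rows of the block's class carry it, each cell
    independently with probability ``coherence`` (background draw otherwise).
    ``row_indices`` is filled in by :func:`generate` with the realized rows.
    """

    feature_indices: tuple[int, ...]
    level_pattern: tuple[int, ...]
    label: int
    n_rows: int
    coherence: float = 1.0
    row_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.feature_indices) < 3:
            raise ValueError("a planted block needs >= 3 feature columns")
        if len(self.level_pattern) != len(self.feature_indices):
            raise ValueError("level_pattern length must match feature_indices")
        if self.n_rows < 5:
            raise ValueError("a planted block needs >= 5 rows")
        if not (0.0 < self.coherence <= 1.0):
            raise ValueError("coherence must lie in (0, 1]")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError("block label must be +1 (benign) or -1 (malignant)")


@dataclass(frozen=True)
class SynthConfig:
    """Generation settings: class sizes, blocks, background, noise, seed."""

    n_benign: int
    n_malignant: int
    blocks: tuple[PlantedBlock, ...] = ()
    background: Mapping[int, Sequence[float]] | None = None
    label_noise: float = 0.0
    seed: int = 0
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if self.n_benign + self.n_malignant < 10:
            raise ValueError("need at least 10 samples in total")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must lie in [0, 1]")
        n_levels = self.schema.n_levels
        for blk in self.blocks:
            for j, v in zip(blk.feature_indices, blk.level_pattern):
                if not (0 <= j < self.schema.n_features):
                    raise ValueError(f"block feature index {j} out of range")
                if not (0 <= v < n_levels[j]):
                    raise ValueError(
                        f"block level {v} invalid for feature index {j}"
                    )


def _background_draw(
    rng: np.random.Generator,
    schema: FeatureSchema,
    background: Mapping[int, Sequence[float]] | None,
    size: int,
    col: int,
) -> np.ndarray:
    n_levels = schema.n_levels[col]
    probs = None
    if background is not None and col in background:
        probs = np.asarray(background[col], dtype=float)
        if probs.shape != (n_levels,) or not math.isclose(probs.sum(), 1.0):
            raise ValueError(f"background marginal for column {col} malformed")
    return rng.choice(n_levels, size=size, p=probs)


def generate(config: SynthConfig) -> tuple[SampleTable, list[PlantedBlock]]:
    """Draw a sample table from ``config``; bit-reproducible for a fixed seed.

    Returns the table and the planted blocks with their realized row
    indices (the ground truth for recovery tests).  Blocks of the same label
    occupy disjoint row sets; an infeasible placement raises ``ValueError``.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    n = config.n_benign + config.n_malignant
    f = schema.n_features

    values = np.empty((n, f), dtype=np.int64)
    for j in range(f):
        values[:, j] = _background_draw(rng, schema, config.background, n, j)

    # benign rows first, then malignant; mining is order-invariant
    labels = np.concatenate(
        [
            np.full(config.n_benign, BENIGN, dtype=np.int8),
            np.full(config.n_malignant, MALIGNANT, dtype=np.int8),
        ]
    )
    class_rows = {
        BENIGN: np.arange(config.n_benign),
        MALIGNANT: np.arange(config.n_benign, n),
    }

    realized: list[PlantedBlock] = []
    free = {lab: list(rows) for lab, rows in class_rows.items()}
    for blk in config.blocks:
        pool = free[blk.label]
        if blk.n_rows > len(pool):
            raise ValueError(
                f"block of {blk.n_rows} rows does not fit in its class "
                f"({len(pool)} unoccupied rows left)"
            )
        chosen = rng.choice(len(pool), size=blk.n_rows, replace=False)
        rows = sorted(int(pool[i]) for i in chosen)
        free[blk.label] = [r for r in pool if r not in set(rows)]
        for i in rows:
            for j, v in zip(blk.feature_indices, blk.level_pattern):
                if blk.coherence >= 1.0 or rng.random() < blk.coherence:
                    values[i, j] = v
        realized.append(replace(blk, row_indices=tuple(rows)))

    if config.label_noise > 0:
        flip = rng.random(n) < config.label_noise
        labels = np.where(flip, -labels, labels).astype(np.int8)

    return SampleTable(values, labels, schema), realized


def matching_rows(table: SampleTable, block: PlantedBlock) -> np.ndarray:
    """All rows of ``table`` whose scores equal the block's pattern.

    With a random background, rows outside the planted set can match the
    pattern by chance; such rows extend the same column-constant cocluster
    and are indistinguishable from planted rows, so this is the proper
    ground truth for exact-recovery checks.
    """
    cols = np.asarray(block.feature_indices)
    pattern = np.asarray(block.level_pattern)
    hit = (table.values[:, cols] == pattern[np.newaxis, :]).all(axis=1)
    return np.flatnonzero(hit)


def imbalanced_subset(
    table: SampleTable, target_ir: float, seed: int
) -> SampleTable:
    """Down-sample the majority class to a target imbalance ratio.

    The imbalance ratio is (Nmax - Nmin)/Nmin; 0 means balanced.  The
    minority class is untouched; majority rows are dropped by a seeded
    uniform draw without replacement so that the realized ratio is within
    one sample of ``target_ir``.
    """
    if target_ir < 0:
        raise ValueError("target imbalance ratio must be >= 0")
    nb, nm = table.n_benign, table.n_malignant
    if nb == nm:
        maj_label = BENIGN  # tie: nothing to remove anyway
    else:
        maj_label = BENIGN if nb > nm else MALIGNANT
    n_min = min(nb, nm)
    n_maj = max(nb, nm)
    # smallest majority count whose ratio is >= the target (ceiling, with a
    # guard so exactly-representable targets are not bumped up a sample)
    keep_maj = int(np.ceil(n_min * (1.0 + target_ir) - 1e-9))
    if keep_maj > n_maj:
        raise ValueError(
            f"target IR {target_ir} exceeds the table's current IR "
            f"({(n_maj - n_min) / n_min:.4f})"
        )
    rng = np.random.default_rng(seed)
    maj_rows = np.flatnonzero(table.labels == maj_label)
    min_rows = np.flatnonzero(table.labels != maj_label)
    kept = rng.choice(maj_rows, size=keep_maj, replace=False)
    rows = np.sort(np.concatenate([kept, min_rows]))
    return table.subset(rows)


def default_config(
    n_benign: int = 487,
    n_malignant: int = 210,
    coherence: float = 0.9,
    label_noise: float = 0.03,
    seed: int = 0,
) -> SynthConfig:
    """Standard study conditions for end-to-end experiments.

    Class sizes default to the 487/210 benign/malignant composition of the
    larger public breast-ultrasound collection this package targets.  Two
    blocks per class encode clinically typical co-occurrences (oval shape
    with parallel orientation and circumscribed, distinct margins in benign
    lesions; irregular shape, non-parallel orientation and spiculated or
    microlobulated margins in malignant ones), each covering 45% of its
    class.  Coherence 0.9 and 3% label noise emulate inter-reader scoring
    variability; the background is uniform per descriptor.
    """
    schema = default_schema()
    idx = {name: i for i, name in enumerate(schema.names)}

    def rows_for(frac: float, n_class: int) -> int:
        return max(5, int(round(frac * n_class)))

    blocks = (
        PlantedBlock(
            feature_indices=(
                idx["Shape"],
                idx["Orientation"],
                idx["Margin integrality"],
                idx["Margin ambiguity"],
                idx["Edema"],
            ),
            level_pattern=(0, 0, 0, 0, 0),
            label=BENIGN,
            n_rows=rows_for(0.45, n_benign),
            coherence=coherence,
        ),
        PlantedBlock(
            feature_indices=(
                idx["Echo pattern"],
                idx["Posterior feature"],
                idx["Calcification in mass"],
                idx["Skin thickening"],
            ),
            level_pattern=(0, 0, 0, 0),
            label=BENIGN,
            n_rows=rows_for(0.45, n_benign),
            coherence=coherence,
        ),
        PlantedBlock(
            feature_indices=(
                idx["Shape"],
                idx["Orientation"],
                idx["Spiculated"],
                idx["Margin integrality"],
            ),
            level_pattern=(2, 1, 1, 1),
            label=MALIGNANT,
            n_rows=rows_for(0.45, n_malignant),
            coherence=coherence,
        ),
        PlantedBlock(
            feature_indices=(
                idx["Echo pattern"],
                idx["Microlobulated"],
                idx["Angular"],
                idx["Architectural distortion"],
            ),
            level_pattern=(5, 1, 1, 1),
            label=MALIGNANT,
            n_rows=rows_for(0.45, n_malignant),
            coherence=coherence,
        ),
    )
    return SynthConfig(
        n_benign=n_benign,
        n_malignant=n_malignant,
        blocks=blocks,
        label_noise=label_noise,
        seed=seed,
        schema=schema,
    )
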