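"""Labeled samples, dataset splitting, class weights and the training stream.

Enzymes are labeled by their first-level Enzyme Commission (EC) class,
an integer 1-6 (oxidoreductase, transferase, hydrolase, lyase, isomerase,
ligase). Labels are supplied as a two-column CSV (``structure_id,
ec_class``); they are not read from PDB headers.

The EC classes are heavily imbalanced in the PDB, so the loss can be
weighted per class by ``w_i = max_j(count_j) / count_i`` computed on the
training portion: the largest class gets weight 1 and under-represented
classes are up-weighted in inverse proportion to their size.

During training each sample is voxelized anew on every pass with an
independently drawn flip code — each axis is flipped with probability
``p_flip`` (default 0.2, so roughly half the samples, 1 - 0.8^3 = 48.8%,
receive at least one flip per pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .structure_io import BackboneTrace, parse_pdb
from .voxelizer import (
    FlipCode,
    VoxelGrid,
    VoxelizerConfig,
    canonical_coords,
    grid_from_canonical,
)

__all__ = [
    "N_CLASSES",
    "LabeledSample",
    "DatasetSplit",
    "ClassWeights",
    "load_labels",
    "load_trace",
    "split_dataset",
    "persist_split",
    "class_counts",
    "compute_class_weights",
    "one_hot",
    "draw_flip_code",
    "training_stream",
]

N_CLASSES = 6


@dataclass(frozen=True)
class LabeledSample:
    """One enzyme: structure id, EC class 1-6, and its coordinate source.

    ``source`` is either a path to a PDB file or an in-memory
    :class:`~enzyvox.structure_io.BackboneTrace` (fixture handle).
    """

    structure_id: str
    ec_class: int
    source: Path | BackboneTrace

    def __post_init__(self) -> None:
        if not 1 <= self.ec_class <= N_CLASSES:
            raise ValueError(
                f"ec_class must be in [1, {N_CLASSES}], got {self.ec_class}"
            )


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test partitions."""

    train: list[LabeledSample]
    validation: list[LabeledSample]
    test: list[LabeledSample]

    def __post_init__(self) -> None:
        ids = [s.structure_id for part in (self.train, self.validation, self.test)
               for s in part]
        if len(ids) != len(set(ids)):
            raise ValueError("split parts must be disjoint by structure_id")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; the largest class has weight exactly 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} weights")
        if not np.all(w >= 1.0) or w.min() != 1.0:
            raise ValueError("weights must be >= 1 with minimum exactly 1")

    @classmethod
    def uniform(cls) -> "ClassWeights":
        return cls(np.ones(N_CLASSES))


def load_labels(labels_csv: str | Path, pdb_dir: str | Path) -> list[LabeledSample]:
    """Read a ``structure_id,ec_class`` CSV into labeled samples.

    Structures appearing with more than one EC class (multi-label enzymes)
    are rejected with a warning; multi-label classification is out of
    scope for this classifier.
    """
    pdb_dir = Path(pdb_dir)
    df = pd.read_csv(labels_csv, dtype={"structure_id": str, "ec_class": int})
    if set(df.columns) < {"structure_id", "ec_class"}:
        raise ValueError("labels CSV must have columns structure_id, ec_class")
    multi = df.groupby("structure_id")["ec_class"].nunique()
    multi_ids = set(multi[multi > 1].index)
    if multi_ids:
        warnings.warn(
            f"rejecting {len(multi_ids)} multi-label structure(s): "
            f"{sorted(multi_ids)[:5]}...",
            stacklevel=2,
        )
        df = df[~df["structure_id"].isin(multi_ids)]
    df = df.drop_duplicates("structure_id")
    return [
        LabeledSample(row.structure_id, int(row.ec_class),
                      pdb_dir / f"{row.structure_id}.pdb")
        for row in df.itertuples()
    ]


def load_trace(sample: LabeledSample, backbone_atoms=None) -> BackboneTrace:
    """Materialize the backbone trace of a sample (parse PDB if needed)."""
    if isinstance(sample.source, BackboneTrace):
        return sample.source
    kwargs = {} if backbone_atoms is None else {"backbone_atoms": backbone_atoms}
    return parse_pdb(sample.source, structure_id=sample.structure_id, **kwargs)


def split_dataset(samples: Sequence[LabeledSample], seed: int) -> DatasetSplit:
    """Random unstratified 64/16/20% train/validation/test split.

    The data is first split 80/20 into a training pool and a test set,
    then 20% of the pool is held out for validation. Deterministic given
    ``seed``; sizes are rounded to the nearest integer.
    """
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n = len(samples)
    n_test = round(0.2 * n)
    n_val = round(0.2 * (n - n_test))
    shuffled = [samples[i] for i in order]
    return DatasetSplit(
        train=shuffled[n_test + n_val:],
        validation=shuffled[n_test:n_test + n_val],
        test=shuffled[:n_test],
    )


def persist_split(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write the three partitions as plain-text ID lists for audit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, part in (("train", split.train), ("validation", split.validation),
                       ("test", split.test)):
        (out_dir / f"{name}_ids.txt").write_text(
            "".join(f"{s.structure_id}\n" for s in part)
        )


def class_counts(samples: Sequence[LabeledSample]) -> np.ndarray:
    """Number of samples per EC class as a 6-vector."""
    counts = np.zeros(N_CLASSES, dtype=int)
    for s in samples:
        counts[s.ec_class - 1] += 1
    return counts


def compute_class_weights(train_counts: Sequence[int]) -> ClassWeights:
    """Imbalance-adapted weights ``w_i = max_j(count_j) / count_i``."""
    counts = np.asarray(train_counts, dtype=float)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class counts")
    if np.any(counts < 1):
        raise ValueError("every class needs at least one training sample")
    return ClassWeights(counts.max() / counts)


def one_hot(ec_class: int) -> np.ndarray:
    """One-hot label vector for an EC class in [1, 6]."""
    if not 1 <= ec_class <= N_CLASSES:
        raise ValueError(f"ec_class out of range: {ec_class}")
    v = np.zeros(N_CLASSES)
    v[ec_class - 1] = 1.0
    return v


def draw_flip_code(rng: np.random.Generator, p_flip: float) -> FlipCode:
    """Draw each of the three flip indicators independently with ``p_flip``."""
    d = rng.random(3) < p_flip
    return FlipCode(int(d[0]), int(d[1]), int(d[2]))


def training_stream(
    split: DatasetSplit,
    cfg: VoxelizerConfig,
    p_flip: float = 0.2,
    seed: int = 0,
    n_passes: int = 1,
) -> Iterator[tuple[VoxelGrid, np.ndarray]]:
    """Augmented (grid, one-hot label) pairs over the training partition.

    Each pass visits every training sample once in a freshly shuffled
    order; each visit draws an independent flip code (per-axis probability
    ``p_flip``) and voxelizes under it. The flip-independent part of the
    pipeline is computed once per sample and cached, so successive passes
    only pay for the flip and voxel assignment. Fully reproducible given
    ``seed``; per-pass shuffles and flips use streams derived from it so
    epochs differ from each other.
    """
    if not 0.0 <= p_flip <= 1.0:
        raise ValueError("p_flip must be in [0, 1]")
    cache: dict[str, np.ndarray] = {}
    root = np.random.SeedSequence(seed)
    for pass_seq in root.spawn(n_passes):
        rng = np.random.default_rng(pass_seq)
        order = rng.permutation(len(split.train))
        for i in order:
            sample = split.train[i]
            f = draw_flip_code(rng, p_flip)
            try:
                coords = cache.get(sample.structure_id)
                if coords is None:
                    trace = load_trace(sample, cfg.backbone_atoms)
                    coords = canonical_coords(trace, cfg)
                    cache[sample.structure_id] = coords
                grid = grid_from_canonical(coords, cfg, f,
                                           source_id=sample.structure_id)
            except Exception as exc:
                raise RuntimeError(
                    f"voxelization failed for sample {sample.structure_id!r}"
                ) from exc
            yield grid, one_hot(sample.ec_class)
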