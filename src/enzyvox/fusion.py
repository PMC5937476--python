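"""Test-time decision fusion over flipped copies of a structure.

Because the principal-axis orientation leaves a left-right / bottom-up
ambiguity, the classifier can be queried on several axis-flipped copies
of the same volume and the per-flip outputs fused into one decision:

* ``none`` — classify the unflipped volume only;
* ``flips`` — classify every flipped copy and fuse with equal weight;
* ``weighted_flips`` — fuse with coefficient ``1 / (dx + dy + dz + 1)``
  per flip, favoring copies with fewer flips.

For the two augmented strategies the fusion is either *probability-based*
(argmax of the coefficient-weighted sum of probability vectors) or
*class-based* (weighted majority vote over per-flip argmax classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import N_CLASSES
from .structure_io import BackboneTrace
from .voxelizer import (
    FlipCode,
    IDENTITY_FLIP,
    VoxelizerConfig,
    canonical_coords,
    enumerate_flip_codes,
    grid_from_canonical,
)

__all__ = [
    "DecisionConfig",
    "PredictionResult",
    "flip_weight",
    "fuse_probability",
    "fuse_majority",
    "predict_final",
]


@dataclass(frozen=True)
class DecisionConfig:
    """Fusion strategy selection.

    ``strategy`` is one of ``none`` / ``flips`` / ``weighted_flips``;
    ``mode`` (``probability`` or ``class``) is ignored when strategy is
    ``none``. ``include_identity`` controls whether the unflipped volume
    joins the 7 flipped copies (default True, n = 8).
    """

    strategy: str = "none"
    mode: str = "probability"
    include_identity: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in ("none", "flips", "weighted_flips"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mode not in ("probability", "class"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PredictionResult:
    """Per-flip probabilities and the fused decision for one structure."""

    structure_id: str
    per_flip_probs: np.ndarray  # (n, 6)
    flip_codes: list[FlipCode]
    final_class: int
    fused_scores: np.ndarray  # (6,) aggregation the decision was taken from


def flip_weight(f: FlipCode) -> float:
    """Fusion coefficient ``1 / (dx + dy + dz + 1)``; 1 at the identity."""
    return 1.0 / (f.n_flips + 1)


def _fused_probability_scores(per_flip_probs: np.ndarray,
                              coefficients: np.ndarray) -> np.ndarray:
    return coefficients @ per_flip_probs


def fuse_probability(per_flip_probs: np.ndarray,
                     coefficients: Sequence[float] | None = None) -> int:
    """Probability-based decision: argmax of the weighted probability sum.

    Returns a class in [1, 6]; ties break toward the lowest class index.
    """
    probs = np.atleast_2d(np.asarray(per_flip_probs, dtype=float))
    if probs.size == 0:
        raise ValueError("no per-flip probabilities to fuse")
    coeff = (np.ones(probs.shape[0]) if coefficients is None
             else np.asarray(coefficients, dtype=float))
    if coeff.shape != (probs.shape[0],) or np.any(coeff <= 0):
        raise ValueError("coefficients must be positive, one per flip")
    return int(np.argmax(_fused_probability_scores(probs, coeff))) + 1


def fuse_majority(per_flip_classes: Sequence[int],
                  coefficients: Sequence[float] | None = None,
                  per_flip_probs: np.ndarray | None = None) -> int:
    """Class-based decision: weighted majority vote over per-flip classes.

    Ties are broken by the larger coefficient-weighted summed probability
    (when ``per_flip_probs`` is available), then toward the lowest class
    index.
    """
    classes = np.asarray(per_flip_classes, dtype=int)
    if classes.size == 0:
        raise ValueError("no per-flip classes to fuse")
    if np.any((classes < 1) | (classes > N_CLASSES)):
        raise ValueError("class indices must lie in [1, 6]")
    coeff = (np.ones(classes.shape[0]) if coefficients is None
             else np.asarray(coefficients, dtype=float))
    if coeff.shape != (classes.shape[0],) or np.any(coeff <= 0):
        raise ValueError("coefficients must be positive, one per flip")
    votes = np.zeros(N_CLASSES)
    for c, w in zip(classes, coeff):
        votes[c - 1] += w
    top = np.flatnonzero(np.isclose(votes, votes.max(), rtol=0, atol=1e-12))
    if top.size > 1 and per_flip_probs is not None:
        probs = np.atleast_2d(np.asarray(per_flip_probs, dtype=float))
        sums = coeff @ probs
        top = top[np.isclose(sums[top], sums[top].max(), rtol=0, atol=1e-12)]
    return int(top.min()) + 1


def predict_final(
    model,
    trace: BackboneTrace,
    vox_cfg: VoxelizerConfig | None = None,
    dec_cfg: DecisionConfig | None = None,
) -> PredictionResult:
    """Classify one structure under the configured fusion strategy.

    The structure is voxelized once per flip code in the configured set
    (a single identity grid for strategy ``none``), each grid is run
    through the model with dropout disabled, and the per-flip outputs are
    fused according to the decision config.
    """
    vox_cfg = vox_cfg or VoxelizerConfig()
    dec_cfg = dec_cfg or DecisionConfig()

    if dec_cfg.strategy == "none":
        codes = [IDENTITY_FLIP]
    else:
        codes = enumerate_flip_codes(include_identity=dec_cfg.include_identity)

    coords = canonical_coords(trace, vox_cfg)
    grids = [grid_from_canonical(coords, vox_cfg, f, trace.structure_id)
             for f in codes]
    x = np.stack([g.values for g in grids]).astype(np.float32)[..., None]
    probs = model.predict_proba(x)

    if dec_cfg.strategy == "weighted_flips":
        coeff = np.array([flip_weight(f) for f in codes])
    else:
        coeff = np.ones(len(codes))

    if dec_cfg.strategy != "none" and dec_cfg.mode == "class":
        per_flip_classes = probs.argmax(axis=1) + 1
        final = fuse_majority(per_flip_classes, coeff, probs)
    else:
        final = fuse_probability(probs, coeff)
    return PredictionResult(
        structure_id=trace.structure_id,
        per_flip_probs=probs,
        flip_codes=codes,
        final_class=final,
        fused_scores=_fused_probability_scores(probs, coeff),
    )
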