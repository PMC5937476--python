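"""The two-layer 3-D convolutional classifier and its training loop.

Architecture (valid padding throughout, channels-last):

    32x32x32x1 -> conv 32 filters 9x9x9 stride 2 -> LeakyReLU(0.1) -> dropout
               -> conv 64 filters 5x5x5 stride 1 -> LeakyReLU(0.1)
               -> maxpool 2x2x2 stride 2 -> dropout
               -> flatten (4096) -> dense 128 -> LeakyReLU(0.1) -> dropout
               -> dense 6 -> softmax

With the default sizes this network has exactly 804,614 trainable
parameters (23,360 + 256,064 + 524,416 + 774 for the four weighted
layers). It is trained with Adam on a class-weighted categorical
cross-entropy, with an L2 penalty of strength 0.001 on the convolutional
and dense kernels (biases excluded).

The loss over a set of samples is

    L = - sum_x sum_i w_i * delta_{x,i} * log(p_hat_{x,i})

where ``p_hat_{x,i}`` is the predicted probability that sample ``x``
belongs to class ``i``, ``delta_{x,i}`` indicates its true class, and
``w_i`` is the class weight (all 1 for uniform weighting, or the
imbalance-adapted weights of :func:`enzyvox.dataset.compute_class_weights`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _layers as L
from .dataset import (
    ClassWeights,
    DatasetSplit,
    N_CLASSES,
    class_counts,
    compute_class_weights,
    load_trace,
    one_hot,
    training_stream,
)
from .voxelizer import VoxelGrid, VoxelizerConfig, voxelize

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "ArchitectureError",
    "TrainingDivergedError",
    "VoxelCNN",
    "build_model",
    "count_parameters",
    "weighted_cross_entropy",
    "train",
    "history_to_csv",
    "cross_validate",
]

#: Floor applied to predicted probabilities inside logarithms.
LOG_EPS = 1e-7


class ArchitectureError(ValueError):
    """Raised when the layer shape chain is inconsistent."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes of the classifier; defaults give the 804,614-parameter net."""

    input_edge: int = 32
    input_channels: int = 1
    conv1_filters: int = 32
    conv1_kernel: int = 9
    conv1_stride: int = 2
    conv2_filters: int = 64
    conv2_kernel: int = 5
    conv2_stride: int = 1
    pool_window: int = 2
    dense1_units: int = 128
    n_classes: int = N_CLASSES
    leaky_relu_alpha: float = 0.1
    # dropout sites: after conv1 activation, after the pool, after dense1
    dropout_rates: tuple[float, float, float] = (0.2, 0.3, 0.4)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters.

    ``l2_strength`` is the L2 regularization coefficient on kernels
    (0.001); ``class_weighting`` selects uniform weights or the
    imbalance-adapted weights computed from the training class counts.
    """

    l2_strength: float = 1e-3
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 32
    p_flip: float = 0.2
    class_weighting: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_weighting not in ("uniform", "adapted"):
            raise ValueError("class_weighting must be 'uniform' or 'adapted'")
        if not 0.0 <= self.p_flip <= 1.0:
            raise ValueError("p_flip must be in [0, 1]")
        for name in ("l2_strength", "learning_rate", "beta1", "beta2",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class VoxelCNN:
    """Feed-forward 3-D CNN assembled from :mod:`enzyvox._layers`."""

    def __init__(self, spec: ArchitectureSpec, seed: int,
                 l2_strength: float = 1e-3) -> None:
        self.spec = spec
        self.seed = seed
        self.l2_strength = l2_strength
        rng = np.random.default_rng(seed)

        conv1 = L.Conv3D(spec.input_channels, spec.conv1_filters,
                         spec.conv1_kernel, spec.conv1_stride, rng,
                         l2=l2_strength, name="conv1")
        conv2 = L.Conv3D(spec.conv1_filters, spec.conv2_filters,
                         spec.conv2_kernel, spec.conv2_stride, rng,
                         l2=l2_strength, name="conv2")
        pool = L.MaxPool3D(spec.pool_window, name="pool")

        edge = spec.input_edge
        edge1 = conv1.out_edge(edge)
        if edge1 < 1:
            raise ArchitectureError(f"conv1: kernel does not fit edge {edge}")
        edge2 = conv2.out_edge(edge1)
        if edge2 < 1:
            raise ArchitectureError(f"conv2: kernel does not fit edge {edge1}")
        if edge2 % spec.pool_window:
            raise ArchitectureError(
                f"pool: edge {edge2} not divisible by window {spec.pool_window}")
        edge3 = edge2 // spec.pool_window
        flat = edge3 ** 3 * spec.conv2_filters

        d1, d2, d3 = spec.dropout_rates
        alpha = spec.leaky_relu_alpha
        self.layers: list[L.Layer] = [
            conv1,
            L.LeakyReLU(alpha, name="act1"),
            L.Dropout(d1, name="drop1"),
            conv2,
            L.LeakyReLU(alpha, name="act2"),
            pool,
            L.Dropout(d2, name="drop2"),
            L.Flatten(name="flatten"),
            L.Dense(flat, spec.dense1_units, rng, l2=l2_strength, name="dense1"),
            L.LeakyReLU(alpha, name="act3"),
            L.Dropout(d3, name="drop3"),
            L.Dense(spec.dense1_units, spec.n_classes, rng, l2=l2_strength,
                    name="dense2"),
        ]
        self.shape_chain = (edge, edge1, edge2, edge3, flat,
                            spec.dense1_units, spec.n_classes)

    # -- forward ---------------------------------------------------------

    def logits(self, x: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[..., None]
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def predict_proba(self, x: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities; dropout is active only when ``train``."""
        return _softmax(self.logits(x, train, rng))

    def backward(self, grad: np.ndarray) -> None:
        for i, layer in enumerate(reversed(self.layers)):
            grad = layer.backward(grad, need_input_grad=i < len(self.layers) - 1)

    # -- parameters ------------------------------------------------------

    def params(self) -> list[L.Param]:
        return [p for layer in self.layers for p in layer.params()]

    def l2_penalty(self) -> float:
        return self.l2_strength * sum(layer.l2_sum() for layer in self.layers)

    def layer_parameter_counts(self) -> dict[str, int]:
        return {
            layer.name: sum(p.value.size for p in layer.params())
            for layer in self.layers if layer.params()
        }

    # -- persistence -----------------------------------------------------

    def save(self, out_dir: str | Path, extra_config: dict | None = None) -> None:
        """Write weights (npz) plus a JSON sidecar with the architecture."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for layer in self.layers:
            for attr in ("W", "b"):
                if hasattr(layer, attr):
                    arrays[f"{layer.name}.{attr}"] = getattr(layer, attr).value
        np.savez(out_dir / "weights.npz", **arrays)
        sidecar = {"architecture": asdict(self.spec), "seed": self.seed,
                   "l2_strength": self.l2_strength}
        if extra_config:
            sidecar.update(extra_config)
        (out_dir / "model.json").write_text(
            json.dumps(sidecar, indent=2, default=str))

    @classmethod
    def load(cls, model_dir: str | Path) -> "VoxelCNN":
        model_dir = Path(model_dir)
        sidecar = json.loads((model_dir / "model.json").read_text())
        arch = sidecar["architecture"]
        arch["dropout_rates"] = tuple(arch["dropout_rates"])
        net = cls(ArchitectureSpec(**arch), seed=sidecar["seed"],
                  l2_strength=sidecar["l2_strength"])
        with np.load(model_dir / "weights.npz") as data:
            for layer in net.layers:
                for attr in ("W", "b"):
                    if hasattr(layer, attr):
                        getattr(layer, attr).value[...] = data[f"{layer.name}.{attr}"]
        return net


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0,
                l2_strength: float = 1e-3) -> VoxelCNN:
    """Build the classifier with reproducible Glorot-uniform initialization."""
    return VoxelCNN(spec or ArchitectureSpec(), seed=seed, l2_strength=l2_strength)


def count_parameters(model: VoxelCNN) -> int:
    """Total number of trainable weights and biases."""
    return sum(p.value.size for p in model.params())


def weighted_cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    reduction: str = "sum",
) -> float:
    """Class-weighted categorical cross-entropy.

    ``L = - sum_x sum_i w_i * delta_{x,i} * log(p_hat_{x,i})``, summed
    over samples (``reduction="sum"``) or averaged (``"mean"``). With all
    weights equal to 1 this is the standard categorical cross-entropy.
    Predicted probabilities of zero for a true class are clamped at
    ``LOG_EPS`` with a warning.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have matching shapes")
    if weights is None:
        w = np.ones(probs.shape[1])
    elif isinstance(weights, ClassWeights):
        w = weights.w
    else:
        w = np.asarray(weights, dtype=float)
    true_p = (probs * labels).sum(axis=1)
    if np.any(true_p < LOG_EPS):
        warnings.warn(
            f"predicted probability below {LOG_EPS} for a true class; clamping",
            stacklevel=2,
        )
        true_p = np.clip(true_p, LOG_EPS, None)
    sample_w = labels @ w
    losses = -sample_w * np.log(true_p)
    return float(losses.mean() if reduction == "mean" else losses.sum())


def _grids_to_batch(grids: Sequence[VoxelGrid]) -> np.ndarray:
    return np.stack([g.values for g in grids]).astype(np.float32)[..., None]


def train(
    model: VoxelCNN,
    split: DatasetSplit,
    cfg: TrainingConfig,
    vox_cfg: VoxelizerConfig | None = None,
) -> tuple[VoxelCNN, list[dict]]:
    """Train in place on the split's training partition.

    Minimizes the class-weighted cross-entropy (averaged per batch) plus
    the L2 kernel penalty with Adam. Each epoch consumes one shuffled,
    flip-augmented pass of :func:`enzyvox.dataset.training_stream`.
    Returns the model and a history with one entry per epoch
    (``epoch, train_loss, val_loss, val_accuracy``). Validation metrics
    are computed on unflipped grids with dropout disabled; they are NaN
    when the validation partition is empty.

    Raises :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    if not split.train:
        raise ValueError("training partition is empty")
    vox_cfg = vox_cfg or VoxelizerConfig()

    if cfg.class_weighting == "adapted":
        weights = compute_class_weights(class_counts(split.train))
    else:
        weights = ClassWeights.uniform()
    w32 = weights.w.astype(np.float32)

    # deterministic sub-seeds for the stream, dropout and batch handling
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    stream_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    drop_rng = np.random.default_rng(ss[1])

    val_x = val_y = None
    if split.validation:
        val_x = _grids_to_batch(
            [voxelize(load_trace(s, vox_cfg.backbone_atoms), vox_cfg)
             for s in split.validation])
        val_y = np.stack([one_hot(s.ec_class) for s in split.validation])

    optimizer = L.Adam(model.params(), lr=cfg.learning_rate,
                       beta1=cfg.beta1, beta2=cfg.beta2)
    history: list[dict] = []
    if cfg.epochs == 0:
        return model, history

    stream = training_stream(split, vox_cfg, p_flip=cfg.p_flip,
                             seed=stream_seed, n_passes=cfg.epochs)
    n_train = len(split.train)
    for epoch in range(cfg.epochs):
        batch_losses = []
        pending_g, pending_y = [], []
        for _ in range(n_train):
            g, y = next(stream)
            pending_g.append(g)
            pending_y.append(y)
            if len(pending_g) == cfg.batch_size:
                batch_losses.append(
                    _train_batch(model, optimizer, pending_g, pending_y,
                                 w32, drop_rng))
                pending_g, pending_y = [], []
        if pending_g:
            batch_losses.append(
                _train_batch(model, optimizer, pending_g, pending_y,
                             w32, drop_rng))
        train_loss = float(np.mean(batch_losses))
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch + 1}: {train_loss}")

        val_loss = val_acc = float("nan")
        if val_x is not None:
            probs = model.predict_proba(val_x)
            val_loss = weighted_cross_entropy(probs, val_y, weights,
                                              reduction="mean")
            val_acc = float(
                (probs.argmax(axis=1) == val_y.argmax(axis=1)).mean())
        history.append({"epoch": epoch + 1, "train_loss": train_loss,
                        "val_loss": val_loss, "val_accuracy": val_acc})
    return model, history


def _train_batch(model: VoxelCNN, optimizer: L.Adam,
                 grids: list[VoxelGrid], labels: list[np.ndarray],
                 class_w: np.ndarray, rng: np.random.Generator) -> float:
    x = _grids_to_batch(grids)
    y = np.stack(labels).astype(np.float32)
    probs = model.predict_proba(x, train=True, rng=rng)
    sample_w = y @ class_w
    n = x.shape[0]
    loss = float(-(sample_w * np.log(np.clip((probs * y).sum(axis=1),
                                             LOG_EPS, None))).mean())
    loss += model.l2_penalty()
    # gradient of mean weighted CE through the softmax
    grad = sample_w[:, None] * (probs - y) / n
    model.backward(grad.astype(np.float32))
    optimizer.step()
    return loss


def history_to_csv(history: list[dict], path: str | Path) -> None:
    """Persist the per-epoch training history as CSV."""
    import pandas as pd

    pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss",
                                   "val_accuracy"]).to_csv(path, index=False)


def cross_validate(
    samples,
    cfg: TrainingConfig,
    vox_cfg: VoxelizerConfig | None = None,
    n_folds: int = 5,
    spec: ArchitectureSpec | None = None,
) -> dict:
    """Repeated-split cross-validation of the full training protocol.

    Each fold re-splits the sample pool with a fold-indexed seed, trains
    a fresh model, and records held-out accuracy; results are reported as
    mean +/- sample standard deviation over folds.
    """
    from .dataset import split_dataset
    from .metrics import accuracy, confusion

    accs = []
    for fold in range(n_folds):
        split = split_dataset(samples, seed=cfg.seed + fold)
        model = build_model(spec, seed=cfg.seed + fold,
                            l2_strength=cfg.l2_strength)
        model, _ = train(model, split, cfg, vox_cfg)
        vc = vox_cfg or VoxelizerConfig()
        x = _grids_to_batch(
            [voxelize(load_trace(s, vc.backbone_atoms), vc)
             for s in split.test])
        pred = model.predict_proba(x).argmax(axis=1) + 1
        truth = np.array([s.ec_class for s in split.test])
        accs.append(accuracy(confusion(truth, pred)))
    accs = np.asarray(accs)
    return {"fold_accuracies": accs.tolist(),
            "mean": float(accs.mean()),
            "std": float(accs.std(ddof=1)) if n_folds > 1 else 0.0}
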