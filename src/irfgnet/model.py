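"""The multi-label 1D CNN: architecture, losses, training, inference.

The network maps a length-600 spectrum through repeated
Conv1D -> BatchNorm -> ReLU -> MaxPool blocks, a flatten, fully connected
layers with dropout, and a final dense layer with sigmoid activation giving
one independent presence probability per functional group (37 for the
extended catalog, 22 for the original).

Losses are binary cross-entropy (the default) and weighted binary
cross-entropy, where each class's positive term is up-weighted by its
negative/positive count ratio to counter the heavy presence/absence
imbalance of multi-label group annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .spectra import ProcessedSpectrum
from .synth import LabeledSpectrum, dataset_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ClassWeights",
    "PredictionMatrix",
    "CNNModel",
    "build_model",
    "compute_class_weights",
    "bce_loss",
    "wbce_loss",
    "train",
    "predict_proba",
    "classify",
]

_EPS = 1e-7  # probability clipping inside losses


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Each conv block is (n_filters, kernel_size, pool_size). The default is
    a compact three-block network that trains in minutes on one CPU while
    solving the synthetic task; every size is overridable.
    """

    n_classes: int
    input_length: int = 600
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 9, 2), (32, 9, 2), (64, 9, 2))
    fc_sizes: tuple[int, ...] = (128,)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not self.conv_blocks or not self.fc_sizes:
            raise ValueError("need at least one conv block and one FC layer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        length = self.input_length
        for i, (nf, k, pool) in enumerate(self.conv_blocks):
            if k % 2 == 0 or nf < 1 or pool < 1:
                raise ValueError(f"conv block {i}: filters >= 1, odd kernel, pool >= 1")
            length //= pool
            if length == 0:
                raise ValueError(
                    f"conv block {i} (pool {pool}) reduces the sequence length to 0"
                )

    @property
    def flat_size(self) -> int:
        length = self.input_length
        for _, _, pool in self.conv_blocks:
            length //= pool
        return length * self.conv_blocks[-1][0]


@dataclass
class TrainConfig:
    seed: int
    loss: str = "bce"
    epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    early_stopping_patience: int | None = None
    weight_cap: float = 100.0  # cap for classes with no positives

    def __post_init__(self) -> None:
        if self.loss not in ("bce", "wbce"):
            raise ValueError(f"loss must be 'bce' or 'wbce', got {self.loss!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, learning_rate > 0 required")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class ClassWeights:
    """Per-class loss weights; unit weights reduce WBCE to plain BCE."""

    w_pos: np.ndarray
    w_neg: np.ndarray

    def __post_init__(self) -> None:
        self.w_pos = np.asarray(self.w_pos, dtype=float)
        self.w_neg = np.asarray(self.w_neg, dtype=float)
        if self.w_pos.shape != self.w_neg.shape:
            raise ValueError("w_pos and w_neg must have identical shapes")
        if (self.w_pos < 0).any() or (self.w_neg < 0).any() or \
                not np.isfinite(self.w_pos).all() or not np.isfinite(self.w_neg).all():
            raise ValueError("class weights must be finite and nonnegative")

    @classmethod
    def unit(cls, n_classes: int) -> "ClassWeights":
        return cls(np.ones(n_classes), np.ones(n_classes))


@dataclass
class PredictionMatrix:
    """Sigmoid outputs: one presence probability per sample and class."""

    probs: np.ndarray
    ids: list[str]
    catalog_ref: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D (n_samples x n_classes)")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


class CNNModel:
    """A built (possibly trained) network plus its configuration."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(rng.integers(2**31))
        layers: list[_nn.Layer] = []
        c_in = 1
        for nf, k, pool in config.conv_blocks:
            layers += [
                _nn.Conv1D(c_in, nf, k, rng),
                _nn.BatchNorm1D(nf),
                _nn.ReLU(),
                _nn.MaxPool1D(pool),
            ]
            c_in = nf
        layers.append(_nn.Flatten())
        n_in = config.flat_size
        for size in config.fc_sizes:
            layers += [
                _nn.Dense(n_in, size, rng),
                _nn.ReLU(),
                _nn.Dropout(config.dropout_rate, self.dropout_rng),
            ]
            n_in = size
        layers.append(_nn.Dense(n_in, config.n_classes, rng))
        self.layers = layers
        self.catalog_variant: str = ""
        self.grid_spec: dict = {}
        self.thresholds: np.ndarray | None = None
        self.train_seed: int | None = None

    @property
    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers for _, p, _ in lay.params())

    def _forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        _nn.set_train_mode(self.layers, train)
        h = x.astype(_nn.F)
        for lay in self.layers:
            h = lay.forward(h)
        return h

    def _backward(self, grad: np.ndarray) -> None:
        g = grad.astype(_nn.F)
        for lay in reversed(self.layers):
            g = lay.backward(g)

    def predict_proba_array(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probabilities for an (n, input_length) intensity matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected spectra of length {self.config.input_length}, got {X.shape[1]}"
            )
        out = []
        for i in range(0, len(X), batch_size):
            z = self._forward_logits(X[i : i + batch_size, None, :], train=False)
            out.append(_nn.sigmoid(z.astype(float)))
        return np.concatenate(out) if out else np.zeros((0, self.config.n_classes))

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz with weights, buffers and embedded configuration."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self.layers):
            for name, p, _ in lay.params():
                arrays[f"layer{i}.{name}"] = p
            for name, buf in lay.state().items():
                arrays[f"layer{i}.{name}"] = buf
        if self.thresholds is not None:
            arrays["thresholds"] = self.thresholds
        meta = {
            "model_config": asdict(self.config),
            "seed": self.seed,
            "train_seed": self.train_seed,
            "catalog_variant": self.catalog_variant,
            "grid_spec": self.grid_spec,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNNModel":
        path = Path(path)
        try:
            data = np.load(path)
            meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        except Exception as exc:
            raise ValueError(f"cannot load model file {path}: {exc}") from exc
        mc = meta["model_config"]
        mc["conv_blocks"] = tuple(tuple(b) for b in mc["conv_blocks"])
        mc["fc_sizes"] = tuple(mc["fc_sizes"])
        model = cls(ModelConfig(**mc), seed=meta.get("seed", 0))
        for i, lay in enumerate(model.layers):
            for name, p, _ in lay.params():
                p[...] = data[f"layer{i}.{name}"]
            for name, buf in lay.state().items():
                buf[...] = data[f"layer{i}.{name}"]
        if "thresholds" in data:
            model.thresholds = data["thresholds"]
        model.train_seed = meta.get("train_seed")
        model.catalog_variant = meta.get("catalog_variant", "")
        model.grid_spec = meta.get("grid_spec", {})
        return model


def build_model(config: ModelConfig, seed: int = 0) -> CNNModel:
    """Instantiate the network with seeded weight initialization."""
    return CNNModel(config, seed=seed)


def compute_class_weights(labels: np.ndarray, cap: float = 100.0) -> ClassWeights:
    """Imbalance weights: w_pos[c] = (#negatives / #positives), w_neg[c] = 1.

    Classes with no positives get ``cap`` with a warning (their positive
    term never fires in training anyway).
    """
    Y = np.asarray(labels)
    if Y.ndim != 2:
        raise ValueError("labels must be an (n_samples, n_classes) matrix")
    n = len(Y)
    pos = Y.sum(axis=0).astype(float)
    neg = n - pos
    w_pos = np.empty_like(pos)
    zero = pos == 0
    if zero.any():
        logger.warning(
            "classes %s have no positives; capping their weight at %g",
            np.flatnonzero(zero).tolist(), cap,
        )
    w_pos[zero] = cap
    w_pos[~zero] = np.minimum(neg[~zero] / pos[~zero], cap)
    return ClassWeights(w_pos=w_pos, w_neg=np.ones_like(w_pos))


def wbce_loss(probs: np.ndarray, labels: np.ndarray, weights: ClassWeights) -> float:
    """Weighted binary cross-entropy, natural log, mean over samples & classes.

    loss = -mean[ w_pos[c] * y * log p  +  w_neg[c] * (1-y) * log(1-p) ],
    with p clipped to [1e-7, 1 - 1e-7]. All-unit weights give plain BCE.
    """
    P = np.asarray(probs, dtype=float)
    Y = np.asarray(labels, dtype=float)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: probs {P.shape} vs labels {Y.shape}")
    if P.ndim != 2 or P.shape[1] != weights.w_pos.shape[0]:
        raise ValueError("weights not aligned with the class axis")
    Pc = np.clip(P, _EPS, 1 - _EPS)
    terms = weights.w_pos * Y * np.log(Pc) + weights.w_neg * (1 - Y) * np.log(1 - Pc)
    return float(-terms.mean())


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted binary cross-entropy (unit-weight WBCE)."""
    P = np.asarray(probs, dtype=float)
    return wbce_loss(P, labels, ClassWeights.unit(P.shape[-1]))


def _loss_grad_logits(
    probs: np.ndarray, labels: np.ndarray, weights: ClassWeights
) -> np.ndarray:
    """d(mean WBCE)/d(logits); the sigmoid is folded in analytically."""
    n, k = probs.shape
    y = labels
    g = -(weights.w_pos * y * (1.0 - probs) - weights.w_neg * (1.0 - y) * probs)
    return g / (n * k)


def train(
    train_data: Sequence[LabeledSpectrum] | tuple[np.ndarray, np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[CNNModel, list[dict]]:
    """Train the CNN by minibatch Adam on BCE or WBCE.

    A ``validation_fraction`` split is held out (seeded shuffle) for the
    per-epoch validation loss; optional early stopping monitors it. Returns
    the trained model and a per-epoch log of train/validation losses.
    """
    if isinstance(train_data, tuple):
        X, Y = train_data
        X, Y = np.asarray(X, dtype=float), np.asarray(Y)
    else:
        if len(train_data) == 0:
            raise ValueError("empty training dataset")
        X, Y, _ = dataset_arrays(list(train_data))
    if len(X) == 0:
        raise ValueError("empty training dataset")
    if X.shape[1] != model_config.input_length or Y.shape[1] != model_config.n_classes:
        raise ValueError("training data inconsistent with model config")

    rng = np.random.default_rng(train_config.seed)
    model = CNNModel(model_config, seed=train_config.seed)
    model.train_seed = train_config.seed

    n = len(X)
    n_val = max(1, int(round(train_config.validation_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    if train_config.loss == "wbce":
        weights = compute_class_weights(Ytr, cap=train_config.weight_cap)
    else:
        weights = ClassWeights.unit(model_config.n_classes)

    opt = _nn.Adam(model.layers, lr=train_config.learning_rate)
    log: list[dict] = []
    best_val, best_epoch = np.inf, 0
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(Xtr), train_config.batch_size):
            idx = order[i : i + train_config.batch_size]
            xb = Xtr[idx][:, None, :]
            yb = Ytr[idx].astype(float)
            logits = model._forward_logits(xb, train=True)
            probs = _nn.sigmoid(logits.astype(float))
            loss = wbce_loss(probs, yb, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "NaN/inf training loss; try a smaller learning_rate "
                    f"(current {train_config.learning_rate:g})"
                )
            model._backward(_loss_grad_logits(probs, yb, weights))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if len(Xval):
            val_probs = model.predict_proba_array(Xval)
            val_loss = wbce_loss(val_probs, Yval.astype(float), weights)
        else:
            val_loss = float("nan")
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train %.5f, val %.5f", epoch, train_loss, val_loss)
        if train_config.early_stopping_patience is not None and len(Xval):
            if val_loss < best_val - 1e-6:
                best_val, best_epoch = val_loss, epoch
            elif epoch - best_epoch >= train_config.early_stopping_patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                break
    return model, log


def predict_proba(
    model: CNNModel, spectra: Sequence[ProcessedSpectrum] | np.ndarray
) -> PredictionMatrix:
    """Deterministic inference (dropout off, batch-norm running stats)."""
    if isinstance(spectra, np.ndarray):
        X = spectra
        ids = [str(i) for i in range(len(np.atleast_2d(X)))]
    else:
        X = np.stack([s.intensities for s in spectra])
        ids = [str(s.meta.get("id", i)) for i, s in enumerate(spectra)]
    probs = model.predict_proba_array(X)
    return PredictionMatrix(probs=probs, ids=ids, catalog_ref=model.catalog_variant)


def classify(probs: PredictionMatrix | np.ndarray, thresholds: np.ndarray | Sequence[float]) -> np.ndarray:
    """Crisp labels: bit = 1 iff probability >= class threshold (ties positive)."""
    P = probs.probs if isinstance(probs, PredictionMatrix) else np.asarray(probs, dtype=float)
    t = np.asarray(
        thresholds.thresholds if hasattr(thresholds, "thresholds") else thresholds,
        dtype=float,
    )
    if t.ndim != 1 or t.shape[0] != P.shape[-1]:
        raise ValueError("one threshold per class required")
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    return (P >= t).astype(np.int8)
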