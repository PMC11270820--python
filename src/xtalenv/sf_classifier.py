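"""Feed-forward classifier on molecular symmetry-function descriptors.

A small MLP — two hidden layers of 25 GeLU units and a softmax output —
mapping standardized descriptor vectors to per-molecule class
probabilities.  Trained with Adam until the training loss converges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .crystal_io import ValidationError
from .symfuncs import DescriptorSet

__all__ = [
    "TrainingConfig",
    "SFClassifierModel",
    "train_sf_classifier",
    "predict_proba",
    "classify",
    "Classification",
]

HIDDEN = (25, 25)


@dataclass
class TrainingConfig:
    learning_rate: float = 5e-3
    max_epochs: int = 500
    batch_size: int = 32
    seed: int = 0
    convergence_tol: float = 1e-5
    holdout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("training hyperparameters must be positive")


@dataclass
class SFClassifierModel:
    """Weights, feature scaler and class names of a trained SF classifier."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    class_names: list[str]
    descriptor_set_hash: str = ""

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def save(self, path: str | Path) -> None:
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "class_names": self.class_names,
            "descriptor_set_hash": self.descriptor_set_hash,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SFClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=[np.array(w) for w in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_std=np.array(d["scaler_std"]),
            class_names=list(d["class_names"]),
            descriptor_set_hash=d["descriptor_set_hash"],
        )


@dataclass
class Classification:
    molecule_id: int
    class_index: int
    class_label: str
    probs: np.ndarray
    tie_flag: bool = False


def _forward(
    X: np.ndarray,
    weights: Sequence[ad.Tensor],
    biases: Sequence[ad.Tensor],
) -> ad.Tensor:
    h = ad.tensor(X)
    for i, (w, b) in enumerate(zip(weights, biases)):
        h = ad.matmul(h, w) + b
        if i < len(weights) - 1:
            h = ad.gelu(h)
    return h  # logits


def predict_proba(model: SFClassifierModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for a batch of descriptor vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValidationError(
            f"descriptor length {X.shape[1]} != model input {model.weights[0].shape[0]}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_std
    logits = _forward(
        Xs, [ad.tensor(w) for w in model.weights], [ad.tensor(b) for b in model.biases]
    ).data
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def classify(
    model: SFClassifierModel,
    X: np.ndarray,
    molecule_ids: Sequence[int] | None = None,
) -> list[Classification]:
    """Argmax classification; exact ties resolve to the lowest class index."""
    probs = predict_proba(model, X)
    if molecule_ids is None:
        molecule_ids = list(range(len(probs)))
    out = []
    for mid, p in zip(molecule_ids, probs):
        best = int(np.argmax(p))  # argmax returns the first (lowest) index on ties
        tie = bool(np.sum(p == p[best]) > 1)
        out.append(
            Classification(
                molecule_id=int(mid),
                class_index=best,
                class_label=model.class_names[best],
                probs=p,
                tie_flag=tie,
            )
        )
    return out


def _init_params(
    sizes: Sequence[int], rng: np.random.Generator
) -> tuple[list[ad.Tensor], list[ad.Tensor]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(ad.parameter(rng.normal(0.0, scale, size=(fan_in, fan_out))))
        biases.append(ad.parameter(np.zeros(fan_out)))
    return weights, biases


def cross_entropy(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    ls = ad.log_softmax(logits)
    picked = ad.pick(ls, np.arange(len(labels)), labels)
    return -picked.mean()


@dataclass
class TrainingReport:
    loss_trajectory: list[float] = field(default_factory=list)
    holdout_accuracy: float = float("nan")
    n_epochs: int = 0
    converged: bool = False


def train_sf_classifier(
    X: np.ndarray,
    y: Sequence[int],
    class_names: Sequence[str],
    config: TrainingConfig | None = None,
    descriptor_set: DescriptorSet | None = None,
) -> tuple[SFClassifierModel, TrainingReport]:
    """Train the 2x25 MLP on labeled descriptors.

    Deterministic given ``config.seed``; features are z-scored with the
    training-split statistics, which are stored in the model.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data contains a single class")
    if y.min() < 0 or y.max() >= len(class_names):
        raise ValidationError("labels out of range of class_names")

    rng = np.random.default_rng(config.seed)
    n = len(X)
    perm = rng.permutation(n)
    n_hold = int(round(config.holdout_fraction * n))
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    Xtr, ytr = X[train_idx], y[train_idx]

    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std[std < 1e-12] = 1.0
    Xtr_s = (Xtr - mean) / std

    sizes = [X.shape[1], *HIDDEN, len(class_names)]
    weights, biases = _init_params(sizes, rng)
    params = [*weights, *biases]
    opt = ad.Adam(params, lr=config.learning_rate)

    report = TrainingReport()
    window: list[float] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr_s))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            loss = cross_entropy(_forward(Xtr_s[idx], weights, biases), ytr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        epoch_loss = float(np.sum(losses) / len(Xtr_s))
        report.loss_trajectory.append(epoch_loss)
        window.append(epoch_loss)
        if len(window) > 10:
            window.pop(0)
            rel = (max(window) - min(window)) / max(abs(window[-1]), 1e-12)
            if rel < config.convergence_tol:
                report.converged = True
                break
    report.n_epochs = len(report.loss_trajectory)

    model = SFClassifierModel(
        weights=[w.data.copy() for w in weights],
        biases=[b.data.copy() for b in biases],
        scaler_mean=mean,
        scaler_std=std,
        class_names=list(class_names),
        descriptor_set_hash=descriptor_set.content_hash() if descriptor_set else "",
    )
    if len(hold_idx):
        pred = predict_proba(model, X[hold_idx]).argmax(axis=1)
        report.holdout_accuracy = float(np.mean(pred == y[hold_idx]))
    return model, report
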