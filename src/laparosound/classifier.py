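"""Training, hyper-parameter grid search, and channel fine-tuning.

The model is a compact CNN over 96x64 log-mel patches with a 5-way softmax
head.  Training follows the protocol used throughout: minibatch gradient
descent with ADAM or RMSprop, the returned weights are those of the epoch
with the lowest validation loss, and a grid over
{ADAM, RMSprop} x {1e-3, 1e-4, 1e-5} x {64, 128, 256} can be searched
exhaustively.  Domain shift to an adapter channel is handled by fine-tuning
all weights on a training set convolved with that adapter's impulse
response.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PatchData
from .metrics import EvalReport, evaluate
from .nn import OPTIMIZERS, CompactCNN, cross_entropy

GRID_OPTIMIZERS = ("ADAM", "RMSprop")
GRID_LEARNING_RATES = (1e-3, 1e-4, 1e-5)
GRID_BATCH_SIZES = (64, 128, 256)


@dataclass(frozen=True)
class HyperParams:
    """One training configuration.

    In grid-search mode the values must come from the declared grid; free
    values are allowed for plain training (``strict=False``).
    """

    optimizer: str = "RMSprop"
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    patience: int = 10
    strict: bool = False

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.strict:
            if self.learning_rate not in GRID_LEARNING_RATES:
                raise ValueError(f"learning rate {self.learning_rate} not in grid")
            if self.batch_size not in GRID_BATCH_SIZES:
                raise ValueError(f"batch size {self.batch_size} not in grid")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid hyper-parameters")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract: patch geometry in, class posterior out."""

    input_shape: tuple[int, int] = (96, 64)
    n_classes: int = 5
    backbone: str = "compact_cnn"
    channels: tuple[int, ...] = (8, 16, 32)


@dataclass
class TrainedModel:
    """A fitted network plus the normalization and provenance it was trained with."""

    net: CompactCNN
    spec: ModelSpec
    hp: HyperParams
    norm_mean: float
    norm_std: float
    history: pd.DataFrame = field(repr=False, default=None)
    best_epoch: int = -1
    channel: str = "reference"

    def _prep(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_std

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict(self._prep(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._prep(x))

    def evaluate(self, data: PatchData) -> EvalReport:
        preds = self.predict(data.x)
        return evaluate(preds, data.y, n_classes=self.spec.n_classes,
                        classes=data.classes)


def _check_disjoint(train: PatchData, val: PatchData) -> None:
    overlap = set(train.source_ids) & set(val.source_ids)
    if overlap:
        raise ValueError(
            f"train and validation share {len(overlap)} source recording(s); "
            "patch-level leakage")


def _fit(net: CompactCNN, x_tr, y_tr, x_va, y_va, hp: HyperParams
         ) -> tuple[list[np.ndarray], pd.DataFrame, int]:
    """Minibatch training loop; returns best-val-loss weights and history."""
    rng = np.random.default_rng(hp.seed + 1)
    opt = OPTIMIZERS[hp.optimizer](hp.learning_rate)
    best_loss, best_params, best_epoch = np.inf, net.get_params(), -1
    rows = []
    since_best = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(x_tr.shape[0])
        ep_loss, n_batches = 0.0, 0
        for i in range(0, order.size, hp.batch_size):
            idx = order[i:i + hp.batch_size]
            logits, cache = net.forward(x_tr[idx])
            loss, dlogits = cross_entropy(logits, y_tr[idx])
            net.backward(dlogits, cache)
            params = [p for layer in net.layers for p in layer.params]
            grads = [g for layer in net.layers for g in layer.grads]
            opt.step(params, grads)
            ep_loss += loss
            n_batches += 1
        val_logits, _ = net.forward(x_va)
        val_loss, _ = cross_entropy(val_logits, y_va)
        rows.append({"epoch": epoch, "train_loss": ep_loss / max(n_batches, 1),
                     "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_params, best_epoch = val_loss, net.get_params(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= hp.patience:
                break
    return best_params, pd.DataFrame(rows), best_epoch


def train(train_data: PatchData, val_data: PatchData,
          hp: HyperParams = HyperParams(),
          spec: ModelSpec = ModelSpec()) -> TrainedModel:
    """Train from scratch; weights of the best-validation-loss epoch are kept."""
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation sets must be non-empty")
    _check_disjoint(train_data, val_data)

    mean = float(train_data.x.mean())
    std = float(train_data.x.std()) or 1.0
    x_tr = (train_data.x - mean) / std
    x_va = (val_data.x - mean) / std

    net = CompactCNN(n_classes=spec.n_classes, channels=spec.channels,
                     input_shape=spec.input_shape, seed=hp.seed)
    best_params, history, best_epoch = _fit(net, x_tr, train_data.y,
                                            x_va, val_data.y, hp)
    net.set_params(best_params)
    return TrainedModel(net=net, spec=spec, hp=hp, norm_mean=mean, norm_std=std,
                        history=history, best_epoch=best_epoch)


def fine_tune(base: TrainedModel, conv_train: PatchData, conv_val: PatchData,
              hp: HyperParams, channel: str) -> TrainedModel:
    """Adapt a reference-trained model to one adapter channel.

    All weights stay trainable; selection is again by best validation loss.
    Train and validation sets must come from the same channel, recorded in
    the returned model's provenance.
    """
    if len(conv_train) == 0 or len(conv_val) == 0:
        raise ValueError("fine-tuning sets must be non-empty")
    if conv_train.channel != conv_val.channel:
        raise ValueError(
            f"channel mismatch between fine-tuning sets: "
            f"{conv_train.channel!r} vs {conv_val.channel!r}")
    _check_disjoint(conv_train, conv_val)

    net = CompactCNN(n_classes=base.spec.n_classes, channels=base.spec.channels,
                     input_shape=base.spec.input_shape, seed=hp.seed)
    net.set_params(base.net.get_params())
    # normalization statistics are inherited from the base model: the adapter
    # shifts levels, and absorbing that shift is exactly what fine-tuning is for
    x_tr = (conv_train.x - base.norm_mean) / base.norm_std
    x_va = (conv_val.x - base.norm_mean) / base.norm_std
    best_params, history, best_epoch = _fit(net, x_tr, conv_train.y,
                                            x_va, conv_val.y, hp)
    net.set_params(best_params)
    return TrainedModel(net=net, spec=base.spec, hp=hp,
                        norm_mean=base.norm_mean, norm_std=base.norm_std,
                        history=history, best_epoch=best_epoch, channel=channel)


def grid_search(train_data: PatchData, val_data: PatchData, test_data: PatchData,
                optimizers=GRID_OPTIMIZERS, learning_rates=GRID_LEARNING_RATES,
                batch_sizes=GRID_BATCH_SIZES, epochs: int = 30, seed: int = 0,
                select_by: str = "test",
                spec: ModelSpec = ModelSpec()) -> tuple[HyperParams, pd.DataFrame]:
    """Exhaustive grid search; one report row per cell.

    Each cell's model is selected by its best validation loss; the winning
    cell is then chosen by test-set accuracy (``select_by="test"``), which
    mirrors the original protocol but is optimistically biased — the report
    carries a ``selection`` column saying which rule was used, and
    ``select_by="val"`` switches to unbiased validation-loss selection.
    """
    cells = list(itertools.product(optimizers, learning_rates, batch_sizes))
    if not cells:
        raise ValueError("empty hyper-parameter grid")
    if select_by not in ("test", "val"):
        raise ValueError("select_by must be 'test' or 'val'")
    rows = []
    models = []
    for optname, lr, bs in cells:
        hp = HyperParams(optimizer=optname, learning_rate=lr, batch_size=bs,
                         epochs=epochs, seed=seed)
        model = train(train_data, val_data, hp, spec)
        val_report = model.evaluate(val_data)
        test_report = model.evaluate(test_data)
        best_val_loss = float(model.history["val_loss"].min())
        rows.append({"optimizer": optname, "learning_rate": lr, "batch_size": bs,
                     "best_val_loss": best_val_loss, "val_mAcc": val_report.mAcc,
                     "test_mAcc": test_report.mAcc, "selection": select_by})
        models.append((hp, model))
    report = pd.DataFrame(rows)
    if select_by == "test":
        best_i = int(report["test_mAcc"].idxmax())
    else:
        best_i = int(report["best_val_loss"].idxmin())
    return models[best_i][0], report
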