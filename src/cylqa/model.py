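"""The 5-class dose-map CNN, its training loop, and 5-fold ensembling.

Architecture (input 2x21x66): a 3x3 stem convolution to 16 channels, then
conv(16->16)+BN+ReLU+2x2 pool, conv(16->32)+BN+ReLU+2x2 pool,
conv(32->64)+BN+ReLU, global average pooling, a 64->128 linear layer,
dropout 0.5, a 128->5 linear layer and softmax.  Pooling uses floor
semantics, so the spatial trace is (21,66) -> (10,33) -> (5,16).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np

from . import nn
from .dataset import ModelInstance, SplitPlan, instances_to_arrays

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "CNN",
    "FoldEnsemble",
    "EPOCH_GRID",
    "BATCH_GRID",
    "LR_GRID",
    "build_cnn",
    "train_fold",
    "crossval_train",
    "predict",
    "grid_search",
    "save_ensemble",
    "load_ensemble",
]

EPOCH_GRID = (300, 400, 500)
BATCH_GRID = (16, 32, 64, 128)
LR_GRID = (0.0001, 0.0005, 0.001, 0.005)


@dataclasses.dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int, int] = (2, 21, 66)
    stem_channels: int = 16
    block_channels: tuple[int, int, int] = (16, 32, 64)
    fc_width: int = 128
    dropout: float = 0.5
    n_classes: int = 5
    paired_stem_init: bool = True


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    batch_size: int = 16
    lr: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.lr < 0:
            raise ValueError("invalid TrainConfig")


class CNN:
    """Forward/backward network over the nn layers, with named trace stages."""

    def __init__(self, config: CNNConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        c0 = config.input_shape[0]
        c1, c2, c3 = config.block_channels
        s = config.stem_channels
        self.stem = nn.Conv2d(c0, s, rng, input_grad=False)
        self.conv1 = nn.Conv2d(s, c1, rng)
        self.bn1 = nn.BatchNorm2d(c1)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.MaxPool2x2()
        self.conv2 = nn.Conv2d(c1, c2, rng)
        self.bn2 = nn.BatchNorm2d(c2)
        self.relu2 = nn.ReLU()
        self.pool2 = nn.MaxPool2x2()
        self.conv3 = nn.Conv2d(c2, c3, rng)
        self.bn3 = nn.BatchNorm2d(c3)
        self.relu3 = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.fc1 = nn.Linear(c3, config.fc_width, rng)
        self.dropout = nn.Dropout(config.dropout, np.random.default_rng(seed + 1))
        self.fc2 = nn.Linear(config.fc_width, config.n_classes, rng)
        self.layers: list[nn.Layer] = [
            self.stem, self.conv1, self.bn1, self.relu1, self.pool1,
            self.conv2, self.bn2, self.relu2, self.pool2,
            self.conv3, self.bn3, self.relu3, self.gap,
            self.fc1, self.dropout, self.fc2,
        ]
        if config.paired_stem_init and c0 == 2 and s == c1:
            # physics-informed start: half the stem filters contrast the two
            # channels (difference detectors for the calculated-vs-measured
            # signal), half pass common-mode structure; the next convolution
            # starts near identity so its batch-norm immediately rescales the
            # faint difference channels to unit variance.  Spatial kernels
            # stay random and everything remains trainable end to end.
            kern = rng.normal(0.0, np.sqrt(2.0 / 9.0),
                              (3, 3, s)).astype(np.float32)
            w = self.stem.params["W"]
            for k in range(s):
                sign = -1.0 if k < s // 2 else 1.0
                w[:, :, 0, k] = kern[:, :, k]
                w[:, :, 1, k] = sign * kern[:, :, k]
            w1 = self.conv1.params["W"]
            w1 *= 0.1
            for k in range(s):
                w1[1, 1, k, k] += 1.0
        # stages whose output shapes form the architecture trace
        self._trace_stages = [
            ("block1", self.relu1), ("pool1", self.pool1),
            ("block2", self.relu2), ("pool2", self.pool2),
            ("block3", self.relu3), ("gap", self.gap),
            ("fc1", self.fc1), ("fc2", self.fc2),
        ]

    def logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        # channels-first at the interface, channels-last internally
        out = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def forward_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return nn.softmax(self.logits(x, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def activation_shapes(self, x: np.ndarray | None = None
                          ) -> list[tuple[int, ...]]:
        """Per-stage output shapes (without the batch axis) on a forward pass."""
        if x is None:
            x = np.zeros((1, *self.config.input_shape), dtype=np.float32)
        out = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))
        traced: dict[int, tuple[int, ...]] = {}
        for layer in self.layers:
            out = layer.forward(out, False)
            shape = tuple(out.shape[1:])
            if len(shape) == 3:  # report channels-first
                shape = (shape[2], shape[0], shape[1])
            traced[id(layer)] = shape
        return [traced[id(layer)] for _, layer in self._trace_stages]

    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params.values())

    def state(self) -> list[dict[str, np.ndarray]]:
        return [lay.state() for lay in self.layers]

    def load_state(self, states: list[dict[str, np.ndarray]]) -> None:
        for lay, st in zip(self.layers, states):
            lay.load_state(st)


def build_cnn(config: CNNConfig = CNNConfig(), seed: int = 0) -> CNN:
    """Build the network and verify the architecture trace against the contract."""
    model = CNN(config, seed)
    expected = [(16, 21, 66), (16, 10, 33), (32, 10, 33), (32, 5, 16),
                (64, 5, 16), (64,), (128,), (5,)]
    if config == CNNConfig():
        got = model.activation_shapes()
        for (name, _), e, g in zip(model._trace_stages, expected, got):
            if e != g:
                raise ValueError(f"layer {name}: expected output {e}, got {g}")
    return model


def _iterate_batches(n: int, batch_size: int,
                     rng: np.random.Generator):
    order = rng.permutation(n)
    for a in range(0, n, batch_size):
        yield order[a:a + batch_size]


def train_fold(model: CNN, x: np.ndarray, y: np.ndarray,
               config: TrainConfig) -> dict:
    """Train one model with Adam on softmax cross-entropy; returns a history."""
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.layers, config.lr)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    losses: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in _iterate_batches(len(x), config.batch_size, rng):
            probs = nn.softmax(model.logits(x[idx], train=True))
            loss = nn.cross_entropy(probs, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {len(losses)}")
            model.backward(nn.softmax_ce_backward(probs, y[idx]))
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        losses.append(epoch_loss / n_seen)
    return {"loss": losses}


@dataclasses.dataclass
class FoldEnsemble:
    """Five fold models whose averaged softmax outputs are the prediction."""

    models: list[CNN]
    fold_val_accuracy: list[float]
    train_config: TrainConfig

    def __post_init__(self) -> None:
        if len(self.models) != 5:
            raise ValueError(f"ensemble must have 5 members, got {len(self.models)}")

    def predict_proba(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        acc = np.zeros((len(x), self.models[0].config.n_classes))
        for model in self.models:
            for a in range(0, len(x), batch):
                acc[a:a + batch] += model.forward_proba(x[a:a + batch])
        return acc / len(self.models)


def predict(ensemble: FoldEnsemble, instances: Sequence[ModelInstance] | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Averaged class probabilities and argmax labels (ties -> lowest index)."""
    if isinstance(instances, np.ndarray):
        x = instances
    else:
        x, _, _ = instances_to_arrays(instances)
    probs = ensemble.predict_proba(x)
    return probs, probs.argmax(axis=1)


def _accuracy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())


def crossval_train(instances: Sequence[ModelInstance], split: SplitPlan,
                   config: TrainConfig = TrainConfig(),
                   cnn_config: CNNConfig = CNNConfig()) -> FoldEnsemble:
    """Train five models, each holding out one fold, and ensemble them.

    Fold membership is resolved through each instance's plan id so augmented
    variants stay with their source plan.
    """
    if len(split.folds) != 5:
        raise ValueError("split must have exactly 5 folds")
    fold_of = {pid: k for k, fold in enumerate(split.folds) for pid in fold}
    x, y, pids = instances_to_arrays(instances)
    fold_idx = np.array([fold_of[p] for p in pids])
    models: list[CNN] = []
    val_acc: list[float] = []
    for k in range(5):
        tr = fold_idx != k
        va = ~tr
        model = build_cnn(cnn_config, seed=config.seed + k)
        fold_cfg = dataclasses.replace(config, seed=config.seed + 1000 * (k + 1))
        train_fold(model, x[tr], y[tr], fold_cfg)
        val_acc.append(_accuracy(model.forward_proba(x[va]), y[va]))
        models.append(model)
    return FoldEnsemble(models=models, fold_val_accuracy=val_acc,
                        train_config=config)


def grid_search(instances: Sequence[ModelInstance], split: SplitPlan,
                epochs_grid: Sequence[int] = EPOCH_GRID,
                batch_grid: Sequence[int] = BATCH_GRID,
                lr_grid: Sequence[float] = LR_GRID,
                seed: int = 0) -> TrainConfig:
    """Pick the configuration with the best mean cross-validation accuracy.

    Selection uses only the training folds (never the test set); ties break
    toward fewest epochs, then smallest batch, then smallest learning rate.
    """
    if not epochs_grid or not batch_grid or not lr_grid:
        raise ValueError("empty hyperparameter grid")
    for e in epochs_grid:
        if e not in EPOCH_GRID:
            raise ValueError(f"epochs {e} outside the stated grid {EPOCH_GRID}")
    for b in batch_grid:
        if b not in BATCH_GRID:
            raise ValueError(f"batch {b} outside the stated grid {BATCH_GRID}")
    for lr in lr_grid:
        if lr not in LR_GRID:
            raise ValueError(f"lr {lr} outside the stated grid {LR_GRID}")
    best: tuple[float, int, int, float] | None = None
    best_cfg: TrainConfig | None = None
    for e in sorted(epochs_grid):
        for b in sorted(batch_grid):
            for lr in sorted(lr_grid):
                cfg = TrainConfig(epochs=e, batch_size=b, lr=lr, seed=seed)
                ens = crossval_train(instances, split, cfg)
                score = float(np.mean(ens.fold_val_accuracy))
                key = (-score, e, b, lr)
                if best is None or key < best:
                    best, best_cfg = key, cfg
    assert best_cfg is not None
    return best_cfg


def save_ensemble(ensemble: FoldEnsemble, out_dir: str | pathlib.Path) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_models": len(ensemble.models),
        "fold_val_accuracy": ensemble.fold_val_accuracy,
        "train_config": dataclasses.asdict(ensemble.train_config),
        "cnn_config": dataclasses.asdict(ensemble.models[0].config),
        "n_parameters": ensemble.models[0].n_parameters(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for k, model in enumerate(ensemble.models):
        arrays = {}
        for i, st in enumerate(model.state()):
            for name, arr in st.items():
                arrays[f"layer{i:02d}.{name}"] = arr
        np.savez(out / f"fold{k}.npz", **arrays)


def load_ensemble(model_dir: str | pathlib.Path) -> FoldEnsemble:
    mdir = pathlib.Path(model_dir)
    manifest = json.loads((mdir / "manifest.json").read_text())
    cc = {k: tuple(v) if isinstance(v, list) else v
          for k, v in manifest["cnn_config"].items()}
    cnn_config = CNNConfig(**cc)
    tc = manifest["train_config"]
    train_config = TrainConfig(**tc)
    models = []
    for k in range(manifest["n_models"]):
        model = CNN(cnn_config, seed=0)
        data = np.load(mdir / f"fold{k}.npz")
        states: list[dict[str, np.ndarray]] = [{} for _ in model.layers]
        for key in data.files:
            layer_part, name = key.split(".", 1)
            states[int(layer_part[5:])][name] = data[key]
        model.load_state(states)
        models.append(model)
    return FoldEnsemble(models=models,
                        fold_val_accuracy=manifest["fold_val_accuracy"],
                        train_config=train_config)
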