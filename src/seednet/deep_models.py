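"""The three 1D deep architectures for seed spectra and their training loop.

Three families, each consuming an ``(N, 1, B)`` batch of reflectance spectra
and emitting class probabilities:

``VGG``
    Two V blocks (two 1x3 convs, each followed by BN + ELU; 16 then 32
    filters), a 2/2 max pool after each block, flatten, a 64-unit dense
    layer (BN + ELU) and the class output layer with softmax.
``RES``
    A 32-filter 1x7 stem (BN, ELU, max pool), four residual blocks with
    filters doubling 32-64-128-256, a global average pool over the spectral
    axis, and one dense output layer.
``INCEPTION``
    A 16-filter 1x3 stem (BN, ELU, max pool), four inception blocks with
    base filters doubling 16-32-64-128 (a max pool between consecutive
    blocks), then the RES-style tail.

All are trained with softmax cross-entropy and SGD momentum; the epoch with
the highest validation accuracy is checkpointed (earliest epoch on ties)
and test metrics are computed with those weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import (
    ELU,
    BatchNorm,
    Conv1d,
    Dense,
    Flatten,
    GlobalAvgPool1d,
    InceptionBlock,
    MaxPool1d,
    Network,
    ResidualBlock,
    SGD,
    softmax_cross_entropy,
)
from .preprocess import DataSplit, LabeledSpectraSet

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "FitResult",
    "build_vgg",
    "build_res",
    "build_inception",
    "build_model",
    "train",
    "evaluate",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("VGG", "RES", "INCEPTION")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network family instance."""

    name: str
    input_len: int
    n_classes: int
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ARCHITECTURES:
            raise ValueError(f"name must be one of {ARCHITECTURES}")
        if self.input_len < 8:
            raise ValueError("input_len must be >= 8 (two 2x poolings)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "input_len": self.input_len,
             "n_classes": self.n_classes, "init_seed": self.init_seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls(**json.loads(text))


@dataclass
class TrainConfig:
    """Source-training protocol: SGD momentum on cross-entropy.

    Defaults are the sample-rich regime (lr 0.001, momentum 0.9, batch 128,
    400 epochs); fine-tuning overrides them (see the transfer module).
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 400
    seed: int = 0
    checkpoint_metric: str = "val_accuracy"
    patience: int | None = None  # stop after this many epochs without val gain

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class FitResult:
    best_weights: dict
    history: list  # per-epoch dicts: epoch, train_loss, train_acc, val_acc
    best_epoch: int
    test_accuracy: float
    confusion: np.ndarray

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def save_history_csv(self, path: str | Path) -> None:
        self.history_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# builders


def _cbe(name: str, cin: int, cout: int, k: int, rng) -> list:
    return [
        (f"{name}_conv", Conv1d(cin, cout, k, rng)),
        (f"{name}_bn", BatchNorm(cout)),
        (f"{name}_elu", ELU()),
    ]


def build_vgg(input_len: int, n_classes: int, seed: int = 0) -> Network:
    spec = ArchitectureSpec("VGG", input_len, n_classes, seed)
    rng = np.random.default_rng(seed)
    layers = []
    layers += _cbe("v1a", 1, 16, 3, rng)
    layers += _cbe("v1b", 16, 16, 3, rng)
    layers.append(("pool1", MaxPool1d(2)))
    layers += _cbe("v2a", 16, 32, 3, rng)
    layers += _cbe("v2b", 32, 32, 3, rng)
    layers.append(("pool2", MaxPool1d(2)))
    flat_width = 32 * (input_len // 2 // 2)
    layers += [
        ("flatten", Flatten()),
        ("fc1", Dense(flat_width, 64, rng)),
        ("fc1_bn", BatchNorm(64)),
        ("fc1_elu", ELU()),
        ("fc2", Dense(64, n_classes, rng)),
    ]
    net = Network(layers, taps={"flatten": "flatten", "Fc1": "fc1_elu", "Fc2": "@softmax"})
    net.spec = spec
    return net


def build_res(input_len: int, n_classes: int, seed: int = 0) -> Network:
    spec = ArchitectureSpec("RES", input_len, n_classes, seed)
    rng = np.random.default_rng(seed)
    layers = _cbe("stem", 1, 32, 7, rng)
    layers.append(("stem_pool", MaxPool1d(2)))
    filters = (32, 64, 128, 256)
    cin = 32
    for i, f in enumerate(filters, start=1):
        layers.append((f"res{i}", ResidualBlock(cin, f, 3, rng)))
        cin = f
    layers += [
        ("avgpool", GlobalAvgPool1d()),
        ("flatten", Flatten()),
        ("fc1", Dense(cin, n_classes, rng)),
    ]
    net = Network(layers, taps={"flatten": "flatten", "Fc1": "@softmax"})
    net.spec = spec
    return net


def build_inception(input_len: int, n_classes: int, seed: int = 0) -> Network:
    spec = ArchitectureSpec("INCEPTION", input_len, n_classes, seed)
    rng = np.random.default_rng(seed)
    layers = _cbe("stem", 1, 16, 3, rng)
    layers.append(("stem_pool", MaxPool1d(2)))
    base_filters = (16, 32, 64, 128)
    cin = 16
    for i, f in enumerate(base_filters, start=1):
        block = InceptionBlock(cin, f, rng)
        layers.append((f"inc{i}", block))
        cin = block.out_channels
        if i < len(base_filters):  # a max pool follows every block but the last
            layers.append((f"incpool{i}", MaxPool1d(2)))
    layers += [
        ("avgpool", GlobalAvgPool1d()),
        ("flatten", Flatten()),
        ("fc1", Dense(cin, n_classes, rng)),
    ]
    net = Network(layers, taps={"flatten": "flatten", "Fc1": "@softmax"})
    net.spec = spec
    return net


_BUILDERS = {"VGG": build_vgg, "RES": build_res, "INCEPTION": build_inception}


def build_model(spec: ArchitectureSpec) -> Network:
    return _BUILDERS[spec.name](spec.input_len, spec.n_classes, spec.init_seed)


# ---------------------------------------------------------------------------
# training and evaluation


def _as_batch(spectra: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(spectra[:, None, :], dtype=np.float32)


def evaluate(
    model: Network, data: LabeledSpectraSet, idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Accuracy and C x C confusion matrix (rows = true class)."""
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("cannot evaluate on an empty index set")
    proba = model.predict_proba(_as_batch(data.spectra[idx]))
    pred = proba.argmax(axis=1)
    true = data.labels[idx]
    c = data.n_classes
    confusion = np.zeros((c, c), dtype=int)
    np.add.at(confusion, (true, pred), 1)
    return float(np.trace(confusion) / idx.size), confusion


def train(
    model: Network,
    data: LabeledSpectraSet,
    split: DataSplit,
    cfg: TrainConfig | None = None,
) -> FitResult:
    """SGD training with per-epoch validation checkpointing.

    Each epoch shuffles the training indices from the seeded stream, runs
    mini-batches of ``cfg.batch_size``, then scores validation accuracy;
    the weights of the best validation epoch (earliest on ties) are
    retained and used for the test metrics.  With ``learning_rate == 0``
    the pass is a dry run: no parameter nor normalization-statistic update,
    so the model is left bit-identical.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    x_all = _as_batch(data.spectra)
    y_all = data.labels
    updating = cfg.learning_rate > 0
    opt = SGD(model.trainable_params(), cfg.learning_rate, cfg.momentum)
    history: list[dict] = []
    best_val, best_epoch, best_weights = -1.0, -1, model.state_dict()
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(split.train_idx)
        losses, correct = [], 0
        for start in range(0, perm.size, cfg.batch_size):
            bidx = perm[start : start + cfg.batch_size]
            logits = model.forward(x_all[bidx], train=updating)
            loss, dlogits = softmax_cross_entropy(logits, y_all[bidx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y_all[bidx]).sum())
            if updating:
                model.backward(dlogits)
                opt.step()
        val_acc, _ = evaluate(model, data, split.val_idx)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": correct / perm.size,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_weights = model.state_dict()
        elif cfg.patience is not None and epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_weights)
    test_acc, confusion = evaluate(model, data, split.test_idx)
    return FitResult(best_weights, history, best_epoch, test_acc, confusion)


def extract_features(
    model: Network, layer_name: str, data: LabeledSpectraSet, idx: np.ndarray
) -> np.ndarray:
    """Deterministic activations at a named feature point.

    ``flatten`` is the convolutional/dense boundary, ``Fc1`` the first dense
    layer post-activation, ``Fc2`` the softmax output (where the
    architecture has two dense layers).
    """
    idx = np.asarray(idx, dtype=int)
    return model.features(_as_batch(data.spectra[idx]), layer_name)


# ---------------------------------------------------------------------------
# checkpoints: one .npz with an embedded ArchitectureSpec JSON header


def save_checkpoint(model: Network, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __spec__=np.array(model.spec.to_json()), **state)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> Network:
    with np.load(Path(path), allow_pickle=False) as archive:
        spec = ArchitectureSpec.from_json(str(archive["__spec__"]))
        model = build_model(spec)
        state = {k: archive[k] for k in archive.files if k != "__spec__"}
    model.load_state_dict(state)
    return model
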