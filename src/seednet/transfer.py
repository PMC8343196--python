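"""Deep transfer learning: weight transplant, layer freezing, fine-tuning.

The source model's convolutional feature extractor is presumed to have
learned spectral patterns shared across crop seeds (common absorption
features of starch, protein and water).  Transfer therefore:

1. rebuilds the source architecture with the target class count;
2. transplants every source weight that fits — when the class counts
   differ only the final dense layer is freshly initialized, when they
   match even the output layer is carried over;
3. freezes everything before the flatten boundary (including batch-norm
   statistics) and fine-tunes the dense head on the small target set with
   a gentler protocol (batch size 3, learning rate 1e-4 by default).

If source and target share no feature structure this procedure can
*hurt* (negative transfer); the experiment harness reports that case
rather than hiding it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deep_models import (
    ArchitectureSpec,
    FitResult,
    TrainConfig,
    build_model,
    load_checkpoint,
    train,
)
from .nn import Network
from .preprocess import DataSplit, LabeledSpectraSet

__all__ = ["TransferPlan", "transplant", "finetune"]


def default_finetune_config(seed: int = 0) -> TrainConfig:
    """Sample-limited fine-tuning protocol: batch 3, lr 1e-4, momentum 0.9."""
    return TrainConfig(learning_rate=1e-4, momentum=0.9, batch_size=3,
                       epochs=400, seed=seed)


@dataclass
class TransferPlan:
    """What to transplant, what to reinitialize, what to freeze."""

    source: Network | str | Path
    target_n_classes: int
    freeze_boundary: str = "flatten"
    reinit_layers: list[str] | None = None  # None = automatic (final layer iff C differs)
    finetune_cfg: TrainConfig = field(default_factory=default_finetune_config)
    seed: int = 0

    def resolve_source(self) -> Network:
        if isinstance(self.source, Network):
            return self.source
        return load_checkpoint(self.source)


def _final_dense_name(model: Network) -> str:
    return next(reversed(model.layers))


def _source_fingerprint(model: Network) -> str:
    h = hashlib.sha256()
    for name, arr in model.state_dict().items():
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def transplant(plan: TransferPlan) -> Network:
    """Build the target model and copy source weights into it.

    Every layer not listed in ``reinit_layers`` receives bit-identical
    source weights; reinitialized layers keep a fresh seeded init.  With
    equal class counts and no forced reinit the whole model — output layer
    included — is transplanted.
    """
    source = plan.resolve_source()
    src_spec: ArchitectureSpec = source.spec
    target_spec = ArchitectureSpec(
        src_spec.name, src_spec.input_len, plan.target_n_classes, init_seed=plan.seed
    )
    target = build_model(target_spec)
    final = _final_dense_name(target)
    if plan.reinit_layers is None:
        reinit = {final} if plan.target_n_classes != src_spec.n_classes else set()
    else:
        reinit = set(plan.reinit_layers)
        if plan.target_n_classes != src_spec.n_classes:
            reinit.add(final)
    unknown = reinit - set(target.layers)
    if unknown:
        raise KeyError(f"reinit_layers name unknown layers: {sorted(unknown)}")
    src_state = source.state_dict()
    for name, arr in target.state_dict().items():
        layer_name = name.split(".", 1)[0]
        if layer_name in reinit:
            continue
        if name not in src_state:
            raise ValueError(f"source checkpoint lacks weights for layer {name!r}")
        if src_state[name].shape != arr.shape:
            raise ValueError(
                f"shape mismatch at layer {name!r}: source {src_state[name].shape} "
                f"vs target {arr.shape} (only the final layer may differ)"
            )
    target.load_state_dict(
        {
            name: (src_state[name] if name.split(".", 1)[0] not in reinit else arr)
            for name, arr in target.state_dict().items()
        }
    )
    target.provenance = {
        "source_fingerprint": _source_fingerprint(source),
        "reinitialized": sorted(reinit),
        "seed": plan.seed,
    }
    return target


def finetune(
    model: Network,
    plan: TransferPlan,
    target_data: LabeledSpectraSet,
    split: DataSplit,
) -> FitResult:
    """Freeze the feature extractor and fine-tune the dense head.

    Gradient updates (and batch-norm statistic updates) touch only layers
    at or after ``plan.freeze_boundary``; everything before it stays
    bit-identical to its transplanted value.
    """
    model.freeze_before(plan.freeze_boundary)
    return train(model, target_data, split, plan.finetune_cfg)
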