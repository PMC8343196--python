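"""Orchestration: model comparison on one split and training-size sweeps.

Every method in a comparison consumes byte-identical split index sets
(asserted by hashing them before and after each fit), so accuracy
differences are attributable to the methods alone.  The size sweep
subsamples each target training set at nested fractions 10%..100% — the
smaller subset is always contained in the larger one for a fixed seed —
and records test accuracy per (dataset, method, fraction, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import fit_lda_grid, fit_mlp_grid, fit_plsda_grid, fit_svm_grid
from .deep_models import TrainConfig, build_inception, build_res, build_vgg, train
from .nn import Network
from .preprocess import DataSplit, LabeledSpectraSet, split_stratified, subsample_training
from .transfer import TransferPlan, default_finetune_config, finetune, transplant

__all__ = ["run_comparison", "run_size_sweep", "plot_sweep", "DEEP_METHODS", "ALL_METHODS"]

DEEP_METHODS = ("VGG", "RES", "INCEPTION")
ALL_METHODS = DEEP_METHODS + ("TRANSFER", "LDA", "PLS-DA", "SVM", "MLP")

_BUILDERS = {"VGG": build_vgg, "RES": build_res, "INCEPTION": build_inception}


def _split_hash(split: DataSplit) -> str:
    h = hashlib.sha256()
    for idx in (split.train_idx, split.val_idx, split.test_idx):
        h.update(np.sort(np.asarray(idx)).astype(np.int64).tobytes())
    return h.hexdigest()


def run_comparison(
    data: LabeledSpectraSet,
    split: DataSplit,
    methods: list[str],
    seed: int = 0,
    deep_cfg: TrainConfig | None = None,
    source_model: Network | None = None,
    finetune_cfg: TrainConfig | None = None,
    mlp_depths: range = range(1, 5),
) -> pd.DataFrame:
    """Fit every requested method on the identical split; one row each."""
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {ALL_METHODS}")
    guard = _split_hash(split)
    deep_cfg = deep_cfg or TrainConfig(seed=seed)
    rows = []
    for method in methods:
        if method in DEEP_METHODS:
            model = _BUILDERS[method](data.n_bands, data.n_classes, seed)
            fit = train(model, data, split, deep_cfg)
            train_acc = fit.history[fit.best_epoch - 1]["train_acc"]
            rows.append(
                {"method": method, "params": f"seed={seed},epochs={deep_cfg.epochs}",
                 "train_accuracy": train_acc,
                 "val_accuracy": fit.history[fit.best_epoch - 1]["val_acc"],
                 "test_accuracy": fit.test_accuracy}
            )
        elif method == "TRANSFER":
            if source_model is None:
                raise ValueError("TRANSFER requires source_model")
            plan = TransferPlan(
                source=source_model,
                target_n_classes=data.n_classes,
                finetune_cfg=finetune_cfg or default_finetune_config(seed),
                seed=seed,
            )
            model = transplant(plan)
            fit = finetune(model, plan, data, split)
            rows.append(
                {"method": method,
                 "params": f"frozen<{plan.freeze_boundary},seed={seed}",
                 "train_accuracy": fit.history[fit.best_epoch - 1]["train_acc"],
                 "val_accuracy": fit.history[fit.best_epoch - 1]["val_acc"],
                 "test_accuracy": fit.test_accuracy}
            )
        else:
            fitter = {
                "LDA": fit_lda_grid,
                "PLS-DA": fit_plsda_grid,
                "SVM": fit_svm_grid,
            }.get(method)
            if fitter is not None:
                res = fitter(data, split)
            else:
                res = fit_mlp_grid(data, split, depth_range=mlp_depths, seed=seed)
            rows.append(
                {"method": method, "params": str(res.chosen_params),
                 "train_accuracy": res.train_accuracy,
                 "val_accuracy": res.val_accuracy,
                 "test_accuracy": res.test_accuracy}
            )
        if _split_hash(split) != guard:
            raise RuntimeError(f"method {method} mutated the data split")
    return pd.DataFrame(rows)


def run_size_sweep(
    source_model: Network,
    targets: list[LabeledSpectraSet],
    fractions: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    methods: list[str] = ("TRANSFER", "LDA", "SVM"),
    seeds: tuple = (0, 1, 2, 3, 4),
    ratio: tuple[int, int, int] = (1, 2, 2),
    finetune_cfg: TrainConfig | None = None,
    deep_cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Test accuracy per (dataset, method, fraction, seed), long format.

    Target sets are split at the sample-limited 1:2:2 ratio; training
    subsets are nested across fractions for each seed.
    """
    rows = []
    for data in targets:
        for seed in seeds:
            full_split = split_stratified(data.labels, ratio, seed)
            for fraction in fractions:
                split = subsample_training(full_split, data.labels, float(fraction), seed)
                for method in methods:
                    acc = _fit_one(
                        method, data, split, source_model, seed,
                        finetune_cfg=finetune_cfg, deep_cfg=deep_cfg,
                    )
                    rows.append(
                        {"dataset": data.name, "method": method,
                         "fraction": float(fraction), "seed": seed,
                         "test_accuracy": acc,
                         "n_train": len(split.train_idx)}
                    )
    return pd.DataFrame(rows)


def _fit_one(method, data, split, source_model, seed, finetune_cfg=None, deep_cfg=None):
    if method == "TRANSFER":
        plan = TransferPlan(
            source=source_model,
            target_n_classes=data.n_classes,
            finetune_cfg=finetune_cfg or default_finetune_config(seed),
            seed=seed,
        )
        return finetune(transplant(plan), plan, data, split).test_accuracy
    if method in DEEP_METHODS:
        model = _BUILDERS[method](data.n_bands, data.n_classes, seed)
        cfg = deep_cfg or TrainConfig(seed=seed)
        return train(model, data, split, cfg).test_accuracy
    if method == "LDA":
        return fit_lda_grid(data, split).test_accuracy
    if method == "PLS-DA":
        return fit_plsda_grid(data, split).test_accuracy
    if method == "SVM":
        return fit_svm_grid(data, split).test_accuracy
    if method == "MLP":
        return fit_mlp_grid(data, split, depth_range=range(1, 4), seed=seed).test_accuracy
    raise ValueError(f"unknown method {method!r}")


def plot_sweep(report: pd.DataFrame, out_path=None):
    """Median-over-seeds accuracy vs training fraction, one panel per dataset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    datasets = report["dataset"].unique()
    fig, axes = plt.subplots(1, len(datasets), figsize=(4 * len(datasets), 3.2),
                             squeeze=False)
    for ax, ds in zip(axes[0], datasets):
        sub = report[report["dataset"] == ds]
        med = sub.groupby(["method", "fraction"])["test_accuracy"].median().reset_index()
        for method, grp in med.groupby("method"):
            ax.plot(grp["fraction"], grp["test_accuracy"], marker="o", label=method)
        ax.set_title(ds)
        ax.set_xlabel("training fraction")
        ax.set_ylabel("test accuracy")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
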