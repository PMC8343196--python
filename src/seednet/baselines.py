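"""Classical chemometric baselines with validation-selected hyperparameters.

Four conventional multivariate classifiers bracket the deep models:

* LDA — project onto 1..20 discriminant axes (capped at min(20, C-1, B)),
  classify by nearest class centroid in the projected space;
* PLS-DA — partial least squares regression onto one-hot labels with
  1..20 latent variables, class = argmax of the predicted response;
* SVM with an RBF kernel over the 4x4 grid
  C in {10, 100, 1000, 10000} x gamma in {0.1, 0.01, 0.001, 0.0001};
* MLP — fully connected nets over 8 width ladders truncated to 1..4
  hidden layers (32 structures; 24 with depths 1..3 for small target sets).

Every method is selected on validation accuracy so the comparison uses one
criterion throughout.  Spectra are standardized per band (fit on the
training subset only) because SVM-RBF and MLP are scale-sensitive; the
deep models consume raw reflectance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import DataSplit, LabeledSpectraSet

__all__ = [
    "BaselineResult",
    "fit_lda_grid",
    "fit_plsda_grid",
    "fit_svm_grid",
    "fit_mlp_grid",
    "MLP_WIDTH_TABLE",
    "SVM_C_GRID",
    "SVM_GAMMA_GRID",
]

logger = logging.getLogger(__name__)

SVM_C_GRID = (10.0, 100.0, 1000.0, 10000.0)
SVM_GAMMA_GRID = (0.1, 0.01, 0.001, 0.0001)

# width ladders for the deepest (4-hidden-layer) configuration; shallower
# structures take the prefix of each row
MLP_WIDTH_TABLE = (
    (200, 100, 50, 25),
    (180, 90, 45, 23),
    (160, 80, 40, 20),
    (140, 70, 35, 18),
    (120, 60, 30, 15),
    (100, 50, 25, 13),
    (80, 40, 20, 10),
    (60, 30, 15, 8),
)


@dataclass
class BaselineResult:
    method: str
    chosen_params: dict
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    confusion: np.ndarray
    grid_evaluated: list = field(default_factory=list)
    standardized: bool = True
    notes: str = ""


def _standardized_splits(data: LabeledSpectraSet, split: DataSplit):
    scaler = StandardScaler()
    x_train = scaler.fit_transform(data.spectra[split.train_idx])
    x_val = scaler.transform(data.spectra[split.val_idx])
    x_test = scaler.transform(data.spectra[split.test_idx])
    y = data.labels
    return (x_train, y[split.train_idx]), (x_val, y[split.val_idx]), (x_test, y[split.test_idx])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, c: int) -> np.ndarray:
    m = np.zeros((c, c), dtype=int)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def _finish(method, params, predictor, tr, va, te, c, grid, notes="") -> BaselineResult:
    pred_test = predictor(te[0])
    return BaselineResult(
        method=method,
        chosen_params=params,
        train_accuracy=float((predictor(tr[0]) == tr[1]).mean()),
        val_accuracy=float((predictor(va[0]) == va[1]).mean()),
        test_accuracy=float((pred_test == te[1]).mean()),
        confusion=_confusion(te[1], pred_test, c),
        grid_evaluated=grid,
        notes=notes,
    )


def fit_lda_grid(
    data: LabeledSpectraSet, split: DataSplit, n_range: range | None = None
) -> BaselineResult:
    """Scan the number of discriminant axes; nearest-centroid in projection."""
    tr, va, te = _standardized_splits(data, split)
    c, b = data.n_classes, data.n_bands
    if c < 2:
        raise ValueError("need >= 2 classes")
    cap = min(20, c - 1, b)
    candidates = [n for n in (n_range or range(1, 21)) if 1 <= n <= cap]
    notes = ""
    try:
        lda = LinearDiscriminantAnalysis(n_components=cap).fit(tr[0], tr[1])
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto", n_components=cap
        ).fit(tr[0], tr[1])
        notes = "singular within-class scatter: shrinkage fallback"
        logger.warning("LDA %s", notes)
    proj_tr, proj_va = lda.transform(tr[0]), lda.transform(va[0])
    centroids_full = np.stack([proj_tr[tr[1] == k].mean(axis=0) for k in range(c)])

    def predict_at(n, x_proj):
        d = np.linalg.norm(x_proj[:, None, :n] - centroids_full[None, :, :n], axis=2)
        return d.argmin(axis=1)

    grid, best = [], None
    for n in candidates:
        acc = float((predict_at(n, proj_va) == va[1]).mean())
        grid.append({"n_lda": n, "val_accuracy": acc})
        if best is None or acc > best[1]:
            best = (n, acc)
    n_best = best[0]
    predictor = lambda x: predict_at(n_best, lda.transform(x))
    return _finish("LDA", {"n_lda": n_best}, predictor, tr, va, te, c, grid, notes)


def fit_plsda_grid(
    data: LabeledSpectraSet, split: DataSplit, lv_range: range | None = None
) -> BaselineResult:
    """Scan latent variables of a one-hot PLS regression; argmax response."""
    tr, va, te = _standardized_splits(data, split)
    c = data.n_classes
    if c < 2:
        raise ValueError("need >= 2 classes for PLS-DA")
    cap = min(20, data.n_bands, len(tr[1]) - 1)
    candidates = [k for k in (lv_range or range(1, 21)) if 1 <= k <= cap]
    y_onehot = np.eye(c)[tr[1]]
    grid, best = [], None
    for k in candidates:
        pls = PLSRegression(n_components=k, scale=False).fit(tr[0], y_onehot)
        acc = float((pls.predict(va[0]).argmax(axis=1) == va[1]).mean())
        grid.append({"n_lv": k, "val_accuracy": acc})
        if best is None or acc > best[1]:
            best = (k, acc, pls)
    k_best, _, pls = best
    predictor = lambda x: pls.predict(x).argmax(axis=1)
    return _finish("PLS-DA", {"n_lv": k_best}, predictor, tr, va, te, c, grid)


def fit_svm_grid(
    data: LabeledSpectraSet,
    split: DataSplit,
    c_list: tuple = SVM_C_GRID,
    g_list: tuple = SVM_GAMMA_GRID,
) -> BaselineResult:
    """Exhaustive RBF-SVM grid; ties prefer smaller C then larger gamma.

    Multi-class handling is scikit-learn's pairwise (one-vs-one) scheme.
    """
    tr, va, te = _standardized_splits(data, split)
    c = data.n_classes
    grid, best = [], None
    for cc in c_list:
        for g in g_list:
            svc = SVC(C=cc, gamma=g, kernel="rbf").fit(tr[0], tr[1])
            acc = float((svc.predict(va[0]) == va[1]).mean())
            grid.append({"c": cc, "gamma": g, "val_accuracy": acc})
            if best is None or acc > best[1]:
                best = ((cc, g), acc, svc)
    (cc, g), _, svc = best
    return _finish(
        "SVM", {"c": cc, "gamma": g, "multiclass": "one-vs-one"},
        svc.predict, tr, va, te, c, grid,
    )


def fit_mlp_grid(
    data: LabeledSpectraSet,
    split: DataSplit,
    depth_range: range = range(1, 5),
    width_table: tuple = MLP_WIDTH_TABLE,
    seed: int = 0,
    max_iter: int = 400,
) -> BaselineResult:
    """Depth x width-ladder search over fully connected classifiers.

    Each structure is a prefix of one width ladder; training uses the same
    SGD protocol as the deep models (lr 0.001, momentum 0.9) with early
    stopping patience 50 on the training loss.
    """
    tr, va, te = _standardized_splits(data, split)
    c = data.n_classes
    grid, best, skipped = [], None, []
    for depth in depth_range:
        for row in width_table:
            widths = tuple(row[:depth])
            clf = MLPClassifier(
                hidden_layer_sizes=widths,
                solver="sgd",
                learning_rate_init=0.001,
                momentum=0.9,
                max_iter=max_iter,
                n_iter_no_change=50,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                try:
                    clf.fit(tr[0], tr[1])
                except Exception as exc:  # non-convergence: record and move on
                    logger.warning("MLP %s failed: %s", widths, exc)
                    skipped.append(widths)
                    grid.append({"widths": widths, "val_accuracy": None})
                    continue
            acc = float((clf.predict(va[0]) == va[1]).mean())
            grid.append({"widths": widths, "val_accuracy": acc})
            if best is None or acc > best[1]:
                best = (widths, acc, clf)
    if best is None:
        raise RuntimeError("no MLP structure converged")
    widths, _, clf = best
    notes = f"skipped structures: {skipped}" if skipped else ""
    return _finish("MLP", {"hidden_widths": widths}, clf.predict, tr, va, te, c, grid, notes)
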