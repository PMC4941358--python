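"""RBF-kernel SVM training, prediction and cross-validated evaluation.

Evaluation uses the four threshold metrics in their intuitive
misclassification-count form.  Writing N+ and N- for the number of true
positives and true negatives investigated, N-+ for positives predicted
negative and N+- for negatives predicted positive:

    Sn  = 1 - N-+ / N+
    Sp  = 1 - N+- / N-
    Acc = 1 - (N-+ + N+-) / (N+ + N-)
    MCC = [1 - (N-+/N+ + N+-/N-)] /
          sqrt[(1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-)]

This MCC is algebraically the classical Matthews coefficient wherever
both are defined.  Degenerate denominators (all-one-class predictions)
yield an explicit ``None`` marker, never a silent 0.

Protocols: jackknife (leave-one-out; deterministic, partition-free),
stratified k-fold with pooled confusion counts, and an independent test
set.  Cross-validated metrics are computed once from the pooled counts,
not averaged over folds.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix, encode_dataset
from .sequence_io import LabeledDataset

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin SVM with RBF kernel exp(-gamma ||x - y||^2).

    Defaults C=2 and gamma=0.125 are the grid-search optimum for g-gap
    frequency features, which already live in [0, 1] and are used
    unscaled (rescaling would change the meaning of gamma).
    """

    C: float = 2.0
    gamma: float = 0.125
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")


@dataclass
class ConfusionCounts:
    """Misclassification counts: N+, N-, N-+ (missed positives), N+- (false positives)."""

    n_pos: int
    n_neg: int
    pos_as_neg: int  # N-+
    neg_as_pos: int  # N+-

    def __post_init__(self) -> None:
        if not (0 <= self.pos_as_neg <= self.n_pos):
            raise ValueError("need 0 <= N-+ <= N+")
        if not (0 <= self.neg_as_pos <= self.n_neg):
            raise ValueError("need 0 <= N+- <= N-")

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.n_pos + other.n_pos,
            self.n_neg + other.n_neg,
            self.pos_as_neg + other.pos_as_neg,
            self.neg_as_pos + other.neg_as_pos,
        )


@dataclass(frozen=True)
class MetricsSet:
    """Sn, Sp, Acc in [0, 1] and MCC in [-1, 1]; ``None`` marks undefined."""

    sn: float | None
    sp: float | None
    acc: float
    mcc: float | None

    def as_row(self) -> dict:
        fmt = lambda v, p: "NA" if v is None else f"{v:.{p}f}"
        return {
            "Sn_pct": fmt(None if self.sn is None else 100 * self.sn, 2),
            "Sp_pct": fmt(None if self.sp is None else 100 * self.sp, 2),
            "Acc_pct": f"{100 * self.acc:.2f}",
            "MCC": fmt(self.mcc, 3),
        }


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    return ConfusionCounts(
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        pos_as_neg=int(np.sum(pos & (y_pred == -1))),
        neg_as_pos=int(np.sum(~pos & (y_pred == 1))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsSet:
    """Derive Sn/Sp/Acc/MCC from confusion counts.

    Sn (Sp) is ``None`` when the positive (negative) class is absent.
    MCC is ``None`` when either factor under its square root is <= 0,
    which happens exactly when the predictions are all one class.
    """
    n_pos, n_neg = counts.n_pos, counts.n_neg
    fn, fp = counts.pos_as_neg, counts.neg_as_pos
    if n_pos + n_neg == 0:
        raise ValueError("empty confusion counts")
    sn = None if n_pos == 0 else 1.0 - fn / n_pos
    sp = None if n_neg == 0 else 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    mcc: float | None
    if n_pos == 0 or n_neg == 0:
        mcc = None
    else:
        num = 1.0 - (fn / n_pos + fp / n_neg)
        fac1 = 1.0 + (fp - fn) / n_pos
        fac2 = 1.0 + (fn - fp) / n_neg
        mcc = None if fac1 <= 0 or fac2 <= 0 else num / math.sqrt(fac1 * fac2)
    return MetricsSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the encoding and feature subset it expects."""

    estimator: SVC
    subset: np.ndarray  # feature indices trained on, within [0, omega)
    encoding: str
    g: int | None
    omega: int
    config: SVMConfig

    def check_compatible(self, matrix: FeatureMatrix) -> None:
        if matrix.encoding != self.encoding or matrix.omega != self.omega:
            raise ValueError(
                f"matrix encoding {matrix.encoding!r} (omega={matrix.omega}) does not "
                f"match model {self.encoding!r} (omega={self.omega})"
            )
        if matrix.g != self.g:
            raise ValueError(f"matrix g={matrix.g} does not match model g={self.g}")


def _fit_svc(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> SVC:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(C=config.C, gamma=config.gamma, kernel=config.kernel)
    clf.fit(X, y)
    return clf


def _check_subset(subset, omega: int) -> np.ndarray:
    if subset is None:
        return np.arange(omega)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset is empty")
    if subset.min() < 0 or subset.max() >= omega:
        raise ValueError(f"feature subset indices must lie in [0, {omega})")
    return subset


def train(
    matrix: FeatureMatrix,
    subset: Sequence[int] | None = None,
    config: SVMConfig = SVMConfig(),
) -> TrainedModel:
    """Fit an RBF-SVM on the given feature subset (default: all columns)."""
    subset = _check_subset(subset, matrix.omega)
    clf = _fit_svc(matrix.X[:, subset], matrix.labels, config)
    return TrainedModel(
        estimator=clf,
        subset=subset,
        encoding=matrix.encoding,
        g=matrix.g,
        omega=matrix.omega,
        config=config,
    )


def decision_values(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    model.check_compatible(matrix)
    if matrix.X.shape[0] == 0:
        return np.empty(0)
    return model.estimator.decision_function(matrix.X[:, model.subset])


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Binary labels (+1 / -1) by the sign of the decision function.

    An exact tie (decision value 0) goes to the positive class —
    conservative toward sensitivity.
    """
    return _labels_from_decision(decision_values(model, matrix))


def _labels_from_decision(dec: np.ndarray) -> np.ndarray:
    return np.where(dec >= 0, 1, -1)


def _predict_train_test(
    X: np.ndarray, y: np.ndarray, train_idx, test_idx, config: SVMConfig
) -> np.ndarray:
    clf = _fit_svc(X[train_idx], y[train_idx], config)
    return _labels_from_decision(clf.decision_function(X[test_idx]))


def pooled_cv_counts(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[np.ndarray],
    config: SVMConfig,
) -> ConfusionCounts:
    """Train/predict per fold and pool all held-out predictions into one
    confusion-count table (metrics are then computed once, globally)."""
    n = X.shape[0]
    y_pred = np.zeros(n, dtype=int)
    seen = np.zeros(n, dtype=bool)
    for test_idx in folds:
        test_idx = np.asarray(test_idx, dtype=int)
        train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
        y_pred[test_idx] = _predict_train_test(X, y, train_idx, test_idx, config)
        seen[test_idx] = True
    if not seen.all():
        raise ValueError("folds do not cover every sample")
    return confusion_from_predictions(y, y_pred)


def make_folds(
    labels: np.ndarray, k: int, seed: int | None, stratified: bool = True
) -> list[np.ndarray]:
    """Test-index arrays for a k-fold partition, fixed by the seed.

    k equal to the sample count gives the leave-one-out partition
    directly (each sample its own fold), so k-fold with k = M coincides
    with the jackknife exactly.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if k == n:
        return [np.array([i]) for i in range(n)]
    from sklearn.model_selection import KFold, StratifiedKFold

    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in splitter.split(np.zeros(n), labels)]
    if stratified:
        for f in folds:
            if len(np.unique(labels[f])) < 2:
                raise ValueError(
                    "a fold is missing a class; use fewer folds or more samples"
                )
    return folds


def grid_search(
    matrix: FeatureMatrix,
    subset: Sequence[int] | None = None,
    C_grid: Sequence[float] = tuple(2.0**p for p in range(-5, 16, 2)),
    gamma_grid: Sequence[float] = tuple(2.0**p for p in range(-15, 4, 2)),
    k: int = 5,
    seed: int | None = 0,
    stratified: bool = True,
) -> SVMConfig:
    """Pick (C, gamma) maximising pooled k-fold accuracy over a power-of-two
    grid; ties resolve to the smaller C, then the smaller gamma."""
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("grids must be non-empty")
    subset = _check_subset(subset, matrix.omega)
    X = matrix.X[:, subset]
    folds = make_folds(matrix.labels, k, seed, stratified)
    best: tuple[float, float, float] | None = None  # (-acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            config = SVMConfig(C=C, gamma=gamma)
            counts = pooled_cv_counts(X, matrix.labels, folds, config)
            acc = compute_metrics(counts).acc
            key = (-acc, C, gamma)
            if best is None or key < best:
                best = key
    return SVMConfig(C=best[1], gamma=best[2])


def evaluate_counts(counts: ConfusionCounts) -> tuple[MetricsSet, ConfusionCounts]:
    return compute_metrics(counts), counts


def jackknife(
    dataset: LabeledDataset,
    encoding: str = "ggap",
    g: int | None = 1,
    subset: Sequence[int] | None = None,
    config: SVMConfig = SVMConfig(),
    policy: str = "strict",
) -> tuple[MetricsSet, ConfusionCounts]:
    """Leave-one-out evaluation: each sample is predicted by a model
    trained on the other M-1.  Deterministic; no seed, no partition.

    The feature subset is fixed in advance and not re-selected per
    left-out sample, which carries a known selection-bias caveat.
    """
    matrix = encode_dataset(dataset, encoding, g, policy=policy)
    if matrix.X.shape[0] < 3:
        raise ValueError("jackknife needs at least 3 samples")
    subset = _check_subset(subset, matrix.omega)
    folds = [np.array([i]) for i in range(matrix.X.shape[0])]
    counts = pooled_cv_counts(matrix.X[:, subset], matrix.labels, folds, config)
    return compute_metrics(counts), counts


def kfold(
    dataset: LabeledDataset,
    encoding: str = "ggap",
    g: int | None = 1,
    subset: Sequence[int] | None = None,
    config: SVMConfig = SVMConfig(),
    k: int = 5,
    seed: int | None = 0,
    stratified: bool = True,
    policy: str = "strict",
) -> tuple[MetricsSet, ConfusionCounts]:
    """Pooled k-fold cross-validation; the partition is fixed by the seed."""
    matrix = encode_dataset(dataset, encoding, g, policy=policy)
    subset = _check_subset(subset, matrix.omega)
    folds = make_folds(matrix.labels, k, seed, stratified)
    counts = pooled_cv_counts(matrix.X[:, subset], matrix.labels, folds, config)
    return compute_metrics(counts), counts


POSITIVE_VERDICT = "Anticancer peptide"
NEGATIVE_VERDICT = "non-Anticancer peptide"


def independent_test(
    model: TrainedModel,
    test_dataset: LabeledDataset,
    training_dataset: LabeledDataset | None = None,
    policy: str = "strict",
) -> tuple[MetricsSet, ConfusionCounts, list[dict]]:
    """Evaluate a trained model on an independent labelled test set.

    If the training dataset is supplied, exact-sequence overlap with the
    test set triggers a warning (memory advantage), not an error.
    Returns metrics, pooled counts and one verdict row per test peptide.
    """
    if not test_dataset.peptides:
        raise ValueError("empty test set")
    if training_dataset is not None:
        train_seqs = {p.sequence for p in training_dataset.peptides}
        overlap = sum(p.sequence in train_seqs for p in test_dataset.peptides)
        if overlap:
            warnings.warn(
                f"{overlap} test peptide(s) occur verbatim in the training set; "
                "independent-set metrics will be optimistic",
                stacklevel=2,
            )
    matrix = encode_dataset(test_dataset, model.encoding, model.g, policy=policy)
    dec = decision_values(model, matrix)
    y_pred = _labels_from_decision(dec)
    counts = confusion_from_predictions(matrix.labels, y_pred)
    verdicts = [
        {
            "id": pid,
            "decision_value": f"{d:.6f}",
            "verdict": POSITIVE_VERDICT if yp == 1 else NEGATIVE_VERDICT,
        }
        for pid, d, yp in zip(matrix.ids, dec, y_pred)
    ]
    return compute_metrics(counts), counts, verdicts


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a versioned archive (config, subset, encoding,
    fitted estimator)."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "config": model.config,
            "subset": np.asarray(model.subset, dtype=int),
            "encoding": model.encoding,
            "g": model.g,
            "omega": model.omega,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    omega = int(payload["omega"])
    subset = np.asarray(payload["subset"], dtype=int)
    if subset.min() < 0 or subset.max() >= omega:
        raise ValueError("corrupt model archive: subset indices out of range")
    return TrainedModel(
        estimator=payload["estimator"],
        subset=subset,
        encoding=payload["encoding"],
        g=payload["g"],
        omega=omega,
        config=payload["config"],
    )
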