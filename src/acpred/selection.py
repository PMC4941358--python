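"""ANOVA F-value feature ranking and incremental feature selection (IFS).

Each g-gap dipeptide feature is scored by the classical one-way ANOVA
F-value between the positive and negative groups: F = MSB / MSW, where
MSB is the group-size-weighted mean square of group means about the
grand mean (df = K - 1) and MSW the pooled within-group mean square
(df = M - K).  A large F marks a class-relevant feature.

IFS then trains an SVM on growing prefixes S_tau = {f_1 ... f_tau} of
the F-ranked feature list, evaluating each prefix by pooled k-fold
cross-validated accuracy under one frozen fold partition, and picks the
prefix size Theta where the curve peaks (smallest tau on ties).  The
curve is computed for every tau up to the full dimension — it is not
assumed unimodal, so there is no early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import ALPHABET, DIPEPTIDE_NAMES, FeatureMatrix, encode_dataset
from .model_eval import (
    ConfusionCounts,
    MetricsSet,
    SVMConfig,
    compute_metrics,
    make_folds,
    pooled_cv_counts,
)
from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for IFS: fold count, seed, stratification."""

    k: int = 5
    seed: int | None = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class FScoreTable:
    """Per-feature ANOVA F-values with their variance components.

    ``direction`` is +1 where the positive-group mean exceeds the
    negative-group mean, -1 where it is smaller, 0 where equal; it gives
    the enrichment polarity used by the signed heat-map matrix.
    Perfectly separating features (MSW = 0, MSB > 0) carry F = +inf and
    outrank every finite F; constant features (MSB = MSW = 0) carry F = 0.
    """

    f: np.ndarray
    msb: np.ndarray
    msw: np.ndarray
    direction: np.ndarray
    df_between: int
    df_within: int
    feature_names: tuple[str, ...]

    @property
    def omega(self) -> int:
        return self.f.shape[0]


@dataclass
class RankedFeatures:
    """Feature indices in descending-F order; the tau-th prefix is S_tau."""

    order: np.ndarray  # permutation of [0, omega)
    f: np.ndarray  # F-values in ranked (non-increasing) order

    @property
    def omega(self) -> int:
        return self.order.shape[0]

    def prefix(self, tau: int) -> np.ndarray:
        return self.order[:tau]


@dataclass
class IFSResult:
    """The IFS curve and its peak.

    ``metrics[tau - 1]`` holds the pooled cross-validated metrics of the
    SVM trained on the tau-feature prefix; ``theta`` is the smallest tau
    attaining the maximum accuracy.
    """

    taus: np.ndarray
    metrics: list[MetricsSet]
    counts: list[ConfusionCounts]
    theta: int
    ranked: RankedFeatures
    g: int | None = None

    @property
    def acc_curve(self) -> np.ndarray:
        return np.array([m.acc for m in self.metrics])

    @property
    def peak_acc(self) -> float:
        return self.metrics[self.theta - 1].acc

    @property
    def optimal_subset(self) -> np.ndarray:
        return self.ranked.prefix(self.theta)

    def curve_rows(self) -> list[dict]:
        rows = []
        for tau, m in zip(self.taus, self.metrics):
            rows.append({"tau": int(tau), **m.as_row()})
        return rows


def anova_f(matrix: FeatureMatrix, labels: np.ndarray | None = None) -> FScoreTable:
    """One-way ANOVA F-value per feature between the two class groups.

    MSB and MSW are computed with df_B = K - 1 = 1 and df_W = M - K
    degrees of freedom.  Requires both groups non-empty and M >= 3 so
    that df_W >= 1.
    """
    y = matrix.labels if labels is None else np.asarray(labels)
    X = matrix.X
    pos = y == 1
    m1, m2 = int(pos.sum()), int((~pos).sum())
    M, K = m1 + m2, 2
    if m1 == 0 or m2 == 0:
        raise ValueError("both groups must be non-empty")
    if M - K < 1:
        raise ValueError(f"need M >= 3 samples for df_W >= 1, got M={M}")
    grand = X.mean(axis=0)
    mean1 = X[pos].mean(axis=0)
    mean2 = X[~pos].mean(axis=0)
    df_b, df_w = K - 1, M - K
    msb = (m1 * (mean1 - grand) ** 2 + m2 * (mean2 - grand) ** 2) / df_b
    msw = (
        ((X[pos] - mean1) ** 2).sum(axis=0) + ((X[~pos] - mean2) ** 2).sum(axis=0)
    ) / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw > 0, f, np.where(msb > 0, np.inf, 0.0))
    direction = np.sign(mean1 - mean2).astype(int)
    return FScoreTable(
        f=f,
        msb=msb,
        msw=msw,
        direction=direction,
        df_between=df_b,
        df_within=df_w,
        feature_names=matrix.feature_names,
    )


def rank_features(table: FScoreTable) -> RankedFeatures:
    """Order features by descending F; ties break by ascending feature index.

    +inf sentinels sort first (among themselves by index).  The result is
    deterministic and stable across runs on identical input.
    """
    order = np.lexsort((np.arange(table.omega), -table.f))
    return RankedFeatures(order=order, f=table.f[order])


def f_table_rows(table: FScoreTable, ranked: RankedFeatures | None = None) -> list[dict]:
    """Rows for the F-score TSV: dipeptide, F, MSB, MSW, direction, rank."""
    if ranked is None:
        ranked = rank_features(table)
    rank_of = np.empty(table.omega, dtype=int)
    rank_of[ranked.order] = np.arange(1, table.omega + 1)
    return [
        {
            "feature": table.feature_names[u],
            "F": table.f[u],
            "MSB": table.msb[u],
            "MSW": table.msw[u],
            "direction": int(table.direction[u]),
            "rank": int(rank_of[u]),
        }
        for u in range(table.omega)
    ]


def f_matrix_signed(table: FScoreTable):
    """20x20 signed F matrix for the 400 g-gap dipeptides.

    Rows index the first residue and columns the second (alphabetical);
    the entry for dipeptide (a, b) is direction * F, so positive values
    mark dipeptides enriched in the positive class (ACPs) and negative
    values those enriched in the negative class.
    """
    import pandas as pd

    if table.omega != 400:
        raise ValueError(f"signed matrix needs a 400-feature table, got {table.omega}")
    signed = (table.direction * table.f).reshape(20, 20)
    letters = list(ALPHABET)
    return pd.DataFrame(signed, index=letters, columns=letters)


def _restrict_folds(
    folds: Sequence[np.ndarray], kept: np.ndarray
) -> list[np.ndarray]:
    """Map dataset-position folds onto the rows of an encoded matrix that
    kept only ``kept`` positions (skip policy may drop short peptides)."""
    pos_to_row = {int(p): r for r, p in enumerate(kept)}
    out = []
    for fold in folds:
        rows = np.array([pos_to_row[int(p)] for p in fold if int(p) in pos_to_row], int)
        if rows.size:
            out.append(rows)
    return out


def run_ifs(
    dataset: LabeledDataset,
    encoding: str = "ggap",
    g: int | None = 1,
    ranked: RankedFeatures | None = None,
    cv: CVConfig = CVConfig(),
    svm: SVMConfig = SVMConfig(),
    policy: str = "strict",
    folds: Sequence[np.ndarray] | None = None,
) -> IFSResult:
    """Incremental feature selection over the full ranked feature list.

    One fold partition is frozen from the seed and reused for every tau,
    so the curve varies only with the prefix size.  ``folds`` may supply
    a precomputed partition expressed in dataset positions (used to keep
    the partition identical across different g values).
    """
    matrix = encode_dataset(dataset, encoding, g, policy=policy)
    if ranked is None:
        ranked = rank_features(anova_f(matrix))
    if ranked.omega != matrix.omega:
        raise ValueError("ranking does not cover all features of the encoding")
    if folds is None:
        row_folds = make_folds(matrix.labels, cv.k, cv.seed, cv.stratified)
    else:
        row_folds = _restrict_folds(folds, matrix.row_index)
    for fold in row_folds:
        if len(np.unique(matrix.labels[fold])) < 2 and len(fold) > 1:
            raise ValueError("a fold is missing a class")
    X_ranked = matrix.X[:, ranked.order]  # prefix of columns == S_tau
    taus = np.arange(1, matrix.omega + 1)
    metrics: list[MetricsSet] = []
    counts: list[ConfusionCounts] = []
    for tau in taus:
        c = pooled_cv_counts(X_ranked[:, :tau], matrix.labels, row_folds, svm)
        counts.append(c)
        metrics.append(compute_metrics(c))
    acc = np.array([m.acc for m in metrics])
    theta = int(taus[int(np.argmax(acc))])  # argmax returns the first (smallest) peak
    return IFSResult(taus=taus, metrics=metrics, counts=counts, theta=theta,
                     ranked=ranked, g=g if encoding == "ggap" else None)


@dataclass
class GapSelection:
    """Outcome of comparing IFS curves across gap values."""

    best_g: int
    best_result: IFSResult
    per_g: dict[int, IFSResult] = field(default_factory=dict)


def select_best_g(
    dataset: LabeledDataset,
    g_values: Sequence[int] = (0, 1, 2, 3, 4),
    cv: CVConfig = CVConfig(),
    svm: SVMConfig = SVMConfig(),
    policy: str = "strict",
) -> GapSelection:
    """Run the rank-then-IFS pipeline for each gap and keep the best.

    The fold partition is drawn once from the dataset labels and shared
    by every g, so curves differ only through the encoding.  The g whose
    IFS peak accuracy is highest wins; ties go to the smaller g.
    """
    if len(g_values) == 0:
        raise ValueError("g_values must be non-empty")
    folds = make_folds(dataset.labels, cv.k, cv.seed, cv.stratified)
    per_g: dict[int, IFSResult] = {}
    for g in sorted(g_values):
        per_g[g] = run_ifs(
            dataset, "ggap", g, cv=cv, svm=svm, policy=policy, folds=folds
        )
    best_g = max(sorted(per_g), key=lambda g: (per_g[g].peak_acc, -g))
    return GapSelection(best_g=best_g, best_result=per_g[best_g], per_g=per_g)
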