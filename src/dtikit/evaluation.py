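"""Binary-classification evaluation: confusion metrics, ROC/AUC, CV protocols.

Metrics follow the usual confusion-table definitions (accuracy,
sensitivity, specificity, precision, Matthews correlation coefficient);
AUC is the normalized Mann-Whitney U statistic with ties counted 1/2.
Two protocols are provided: stratified k-fold cross-validation with the
feature-selection stage nested inside each training fold, and a
stratified train/independent split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from dtikit.pair_assembly import LabeledPairSet
from dtikit.rotation_forest import RotationForest, RotationForestConfig

METRIC_NAMES = ("Acc", "Sen", "Sp", "Pre", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationReport:
    """Pooled metrics, ROC curve, and per-fold statistics."""

    Acc: float
    Sen: float
    Sp: float
    Pre: float
    MCC: float
    AUC: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    per_fold: dict[str, list[float]] = field(default_factory=dict)
    fold_mean: dict[str, float] = field(default_factory=dict)
    fold_std: dict[str, float] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)
    n_selected: int | None = None

    def as_dict(self) -> dict:
        return {
            "Acc": self.Acc,
            "Sen": self.Sen,
            "Sp": self.Sp,
            "Pre": self.Pre,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "per_fold": self.per_fold,
            "fold_mean": self.fold_mean,
            "fold_std": self.fold_std,
            "degenerate": self.degenerate,
            "n_selected": self.n_selected,
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with class 1 as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only binary 0/1 labels")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> tuple[dict[str, float], list[str]]:
    """Acc, Sen, Sp, Pre and MCC from a confusion table.

    Any zero-denominator metric is reported as 0 and its name returned
    in the degenerate-flag list, so degenerate folds do not abort a run.
    """
    if c.total <= 0:
        raise ValueError("confusion table is empty")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = (c.TN + c.TP) / c.total
    sen = ratio(c.TP, c.TP + c.FN, "Sen")
    sp = ratio(c.TN, c.TN + c.FP, "Sp")
    pre = ratio(c.TP, c.TP + c.FP, "Pre")
    mcc_den = np.sqrt(
        float(c.TN + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TP + c.FN)
    )
    mcc = ratio(c.TN * c.TP - c.FN * c.FP, mcc_den, "MCC")
    return {"Acc": acc, "Sen": sen, "Sp": sp, "Pre": pre, "MCC": mcc}, degenerate


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC via the Mann-Whitney rank statistic, plus the ROC polyline.

    Ties count 1/2.  ROC points sweep every distinct score threshold
    from high to low, starting at (0, 0) and ending at (1, 1).
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # mid-ranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    sorted_scores = s[order]
    sorted_y = y[order]
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_y[j] == 1)
            fp += int(sorted_y[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return float(auc), points


def _fit_and_score(
    pairset: LabeledPairSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    rf_config: RotationForestConfig,
    select: bool,
    bins: int,
    max_rank: int | None,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Select features on the training rows only, fit, and score the test rows."""
    X, y = pairset.X, pairset.y
    cols = np.arange(X.shape[1])
    if select:
        from dtikit.feature_selection import iwssr_select

        result = iwssr_select(
            X[train_idx], y[train_idx], seed=seed, bins=bins, max_rank=max_rank
        )
        cols = np.array(sorted(result.selected))
    forest = RotationForest(rf_config)
    forest.fit(X[np.ix_(train_idx, cols)], y[train_idx])
    scores = forest.positive_scores(X[np.ix_(test_idx, cols)])
    preds = forest.predict(X[np.ix_(test_idx, cols)])
    return preds, scores, len(cols)


def kfold_cv(
    pairset: LabeledPairSet,
    k: int = 10,
    seed: int = 0,
    rf_config: RotationForestConfig | None = None,
    select: bool = False,
    bins: int = 5,
    max_rank: int | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the select-then-classify pipeline.

    Feature selection (when enabled) and model fitting happen inside
    each training fold only.  The report carries metrics of the pooled
    out-of-fold predictions plus the per-fold mean and standard
    deviation of every metric (the error-bar protocol).
    """
    y = pairset.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} members, got {counts.tolist()}")
    rf_config = rf_config or RotationForestConfig(seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    pooled_pred = np.empty_like(y)
    pooled_scores = np.empty(y.size, dtype=float)
    per_fold: dict[str, list[float]] = {m: [] for m in METRIC_NAMES + ("AUC",)}
    degenerate: list[str] = []
    n_selected = None
    for train_idx, test_idx in skf.split(pairset.X, y):
        preds, scores, n_selected = _fit_and_score(
            pairset, train_idx, test_idx, rf_config, select, bins, max_rank, seed
        )
        pooled_pred[test_idx] = preds
        pooled_scores[test_idx] = scores
        fold_metrics, fold_degen = metrics(confusion(y[test_idx], preds))
        degenerate.extend(fold_degen)
        for m in METRIC_NAMES:
            per_fold[m].append(fold_metrics[m])
        if np.unique(y[test_idx]).size == 2:
            fold_auc, _ = roc_auc(y[test_idx], scores)
            per_fold["AUC"].append(fold_auc)

    pooled_metrics, pooled_degen = metrics(confusion(y, pooled_pred))
    degenerate.extend(pooled_degen)
    auc, roc_points = roc_auc(y, pooled_scores)
    return EvaluationReport(
        **pooled_metrics,
        AUC=auc,
        roc_points=roc_points,
        per_fold=per_fold,
        fold_mean={m: float(np.mean(v)) for m, v in per_fold.items() if v},
        fold_std={m: float(np.std(v)) for m, v in per_fold.items() if v},
        degenerate=sorted(set(degenerate)),
        n_selected=n_selected,
    )


def independent_split(
    pairset: LabeledPairSet, train_fraction: float = 0.9, seed: int = 0
) -> tuple[LabeledPairSet, LabeledPairSet]:
    """Stratified, seeded split into a train/test part and an independent part.

    The two parts are disjoint and exhaust the input rows.
    """
    if len(pairset) < 10:
        raise ValueError("independent_split needs at least 10 rows")
    idx = np.arange(len(pairset))
    train_idx, indep_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=pairset.y,
        random_state=seed,
        shuffle=True,
    )
    return pairset.subset(sorted(train_idx)), pairset.subset(sorted(indep_idx))


def evaluate_split(
    train: LabeledPairSet,
    test: LabeledPairSet,
    seed: int = 0,
    rf_config: RotationForestConfig | None = None,
    select: bool = False,
    bins: int = 5,
    max_rank: int | None = None,
) -> EvaluationReport:
    """Select (optionally) and fit on ``train``; report metrics on ``test``."""
    rf_config = rf_config or RotationForestConfig(seed=seed)
    combined = LabeledPairSet(
        train.pair_ids + test.pair_ids,
        np.vstack([train.X, test.X]),
        np.concatenate([train.y, test.y]),
        list(train.feature_names),
    )
    train_idx = np.arange(len(train))
    test_idx = np.arange(len(train), len(combined))
    preds, scores, n_selected = _fit_and_score(
        combined, train_idx, test_idx, rf_config, select, bins, max_rank, seed
    )
    split_metrics, degen = metrics(confusion(test.y, preds))
    auc, roc_points = roc_auc(test.y, scores)
    return EvaluationReport(
        **split_metrics,
        AUC=auc,
        roc_points=roc_points,
        degenerate=degen,
        n_selected=n_selected,
    )
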