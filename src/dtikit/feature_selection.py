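"""Symmetric-uncertainty feature ranking and IWSSR wrapper selection.

The filter stage weights every feature by its symmetric uncertainty
with the class label, SU = 2 * (H(F) - H(F|C)) / (H(F) + H(C)), after
equal-width discretization.  The wrapper stage (incremental wrapper
subset selection with replacement) scans the SU ranking from the top:
for each candidate feature it first tries replacing every feature of
the current subset (swap level), then adding the candidate to the best
subset of the swap level (add level), accepting the best of the two
levels only when it improves the inner evaluator's cross-validated
accuracy by more than a small noise margin.

The default inner evaluator is Gaussian naive Bayes under stratified
10-fold cross-validation — the classical inner classifier of the
incremental wrapper family, whose per-feature log-density decomposition
lets every subset be scored as a cached column sum, so even a
full-ranking scan over thousands of features stays cheap.  A
depth-limited decision-tree evaluator is provided as an alternative;
any callable mapping a feature-index subset to an accuracy in [0, 1]
can be injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier


@dataclass
class SUWeights:
    """Per-feature symmetric-uncertainty values and the descending ranking."""

    values: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if sorted(self.ranking.tolist()) != list(range(len(self.values))):
            raise ValueError("ranking must be a permutation of feature indices")


@dataclass
class SelectionResult:
    """Outcome of the IWSSR search.

    ``selected`` holds feature indices in acceptance order; ``trace``
    records one (candidate, action, score) triple per scanned candidate,
    action in {"add", "swap", "reject"}.
    """

    selected: list[int]
    best_score: float
    trace: list[tuple[int, str, float]] = field(default_factory=list)


def entropy(labels: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def discretize(feature: Sequence[float] | np.ndarray, bins: int = 5) -> np.ndarray:
    """Equal-width binning between min and max into integer codes.

    Features with at most ``bins`` distinct values are passed through as
    dense integer codes; constant features map to a single bin.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(feature, dtype=float)
    uniq = np.unique(x)
    if uniq.size == 1:
        return np.zeros(x.size, dtype=np.int64)
    if uniq.size <= bins:
        return np.searchsorted(uniq, x).astype(np.int64)
    lo, hi = uniq[0], uniq[-1]
    codes = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(codes, bins - 1)


def symmetric_uncertainty(
    feature: Sequence[int] | np.ndarray, classes: Sequence[int] | np.ndarray
) -> float:
    """SU(F, C) = 2 * IG(F; C) / (H(F) + H(C)), in [0, 1].

    IG is the mutual information H(F) - H(F|C).  Returns 0 when the
    denominator is 0 (both variables constant).
    """
    f = np.asarray(feature)
    c = np.asarray(classes)
    if f.shape != c.shape:
        raise ValueError("feature and class vectors must have equal length")
    h_f = entropy(f)
    h_c = entropy(c)
    if h_f + h_c == 0.0:
        return 0.0
    # H(F|C) = sum_c p(c) H(F | C=c)
    h_f_given_c = 0.0
    for value in np.unique(c):
        mask = c == value
        h_f_given_c += mask.mean() * entropy(f[mask])
    su = 2.0 * (h_f - h_f_given_c) / (h_f + h_c)
    return float(min(max(su, 0.0), 1.0))


def rank_features(X: np.ndarray, y: Sequence[int] | np.ndarray, bins: int = 5) -> SUWeights:
    """SU of every column against the labels, ranked descending.

    Ties are broken by ascending column index (stable sort on -SU).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    values = np.array(
        [symmetric_uncertainty(discretize(X[:, j], bins), y) for j in range(X.shape[1])]
    )
    ranking = np.argsort(-values, kind="stable")
    return SUWeights(values, ranking)


def make_nb_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
) -> Callable[[Sequence[int]], float]:
    """Default inner wrapper evaluator: stratified k-fold accuracy of a
    Gaussian naive Bayes classifier on the given feature subset.

    Because naive Bayes log-likelihoods are additive over features, the
    per-row, per-class log-density contribution of every single feature
    is precomputed once per fold; any subset's out-of-fold accuracy is
    then a column sum over those contributions.  Scores are memoized per
    subset and fold assignment is fixed, so subset comparisons are
    consistent across the whole search.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n, d = X.shape
    contrib = np.empty((n, d, classes.size), dtype=np.float32)
    log_priors = np.empty((n, classes.size), dtype=np.float32)
    # variance floor relative to the largest feature variance, as in
    # standard Gaussian-NB smoothing, so constant features stay finite
    eps = 1e-9 * max(X.var(axis=0).max(), 1e-12)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        for ci, c in enumerate(classes):
            rows = train_idx[y[train_idx] == c]
            mu = X[rows].mean(axis=0)
            var = X[rows].var(axis=0) + eps
            contrib[test_idx, :, ci] = (
                -0.5 * np.log(2.0 * np.pi * var) - (X[test_idx] - mu) ** 2 / (2.0 * var)
            )
            log_priors[test_idx, ci] = np.log(rows.size / train_idx.size)
    y_codes = np.searchsorted(classes, y)
    cache: dict[frozenset, float] = {}

    def evaluate(subset: Sequence[int]) -> float:
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        cols = np.fromiter(key, dtype=int)
        scores = contrib[:, cols, :].sum(axis=1) + log_priors
        acc = float((scores.argmax(axis=1) == y_codes).mean())
        cache[key] = acc
        return acc

    return evaluate


def make_tree_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    max_depth: int = 5,
    n_folds: int = 5,
    max_rows: int | None = 2000,
) -> Callable[[Sequence[int]], float]:
    """Alternative inner wrapper evaluator: stratified k-fold accuracy of
    a depth-limited decision tree on the given feature subset.

    Fold assignment is fixed once (seeded), so subset scores are
    comparable across the whole search; scores are memoized per subset.
    When the data exceeds ``max_rows``, a stratified seeded subsample is
    used for the inner cross-validation to bound the wrapper cost.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if max_rows is not None and y.size > max_rows:
        keep, _ = train_test_split(
            np.arange(y.size), train_size=max_rows, stratify=y, random_state=seed
        )
        keep = np.sort(keep)
        X, y = X[keep], y[keep]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    cache: dict[frozenset, float] = {}

    def evaluate(subset: Sequence[int]) -> float:
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        cols = np.fromiter(key, dtype=int)
        correct = 0
        for train_idx, test_idx in folds:
            tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
            tree.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            correct += (tree.predict(X[np.ix_(test_idx, cols)]) == y[test_idx]).sum()
        score = correct / y.size
        cache[key] = score
        return score

    return evaluate


def iwssr_select(
    X: np.ndarray,
    y: Sequence[int] | np.ndarray,
    evaluator: Callable[[Sequence[int]], float] | None = None,
    seed: int = 0,
    bins: int = 5,
    max_rank: int | None = None,
    min_gain: float = 0.01,
) -> SelectionResult:
    """Incremental wrapper subset selection with replacement.

    The SU ranking is scanned from the top.  The subset starts as the
    top-ranked feature.  For each further candidate f, the swap level
    evaluates (S \\ {s}) | {f} for every s in S; the add level evaluates
    the best post-swap subset plus f.  The best candidate of the two
    levels is accepted only if its score strictly exceeds the current
    best by more than ``min_gain`` (ties at the swap level resolve
    toward the smaller replacement position).  ``min_gain`` guards the
    accept decision against the sampling noise of the inner
    cross-validation estimate, which a long ranking scan would otherwise
    exploit by chance; set it to 0 for the bare strict-improvement rule.
    ``max_rank`` optionally limits the scan to the top-m ranked
    features; by default the full ranking is scanned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("IWSSR needs at least two features")
    if evaluator is None:
        evaluator = make_nb_evaluator(X, y, seed=seed)

    ranking = rank_features(X, y, bins).ranking.tolist()
    if max_rank is not None:
        ranking = ranking[:max_rank]

    selected: list[int] = [ranking[0]]
    best_score = float(evaluator(selected))
    if not 0.0 <= best_score <= 1.0:
        raise ValueError(f"evaluator returned accuracy outside [0, 1]: {best_score}")
    trace: list[tuple[int, str, float]] = [(ranking[0], "add", best_score)]

    for f in ranking[1:]:
        # swap level: replace each member of S with f
        swap_score, swap_set = -1.0, None
        for pos in range(len(selected)):
            candidate = selected[:pos] + [f] + selected[pos + 1 :]
            score = float(evaluator(candidate))
            if score > swap_score:
                swap_score, swap_set = score, candidate
        # add level: append f to the best subset of the swap level
        base = swap_set if swap_score > best_score + min_gain else selected
        add_set = base if f in base else base + [f]
        add_score = float(evaluator(add_set))

        if max(swap_score, add_score) > best_score + min_gain:
            if add_score >= swap_score:
                winner, winner_score = add_set, add_score
            else:
                winner, winner_score = swap_set, swap_score
            action = "add" if len(winner) > len(selected) else "swap"
            selected, best_score = winner, winner_score
            trace.append((f, action, winner_score))
        else:
            trace.append((f, "reject", max(swap_score, add_score)))

    return SelectionResult(selected, best_score, trace)
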