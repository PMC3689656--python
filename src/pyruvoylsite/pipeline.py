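"""Dataset balancing, train/test splitting, incremental feature selection
(IFS) with a 10-tree random forest, and the final site classifier.

The raw sample set is heavily imbalanced (one annotated pyruvoyl serine
per protein versus every other serine). Negatives are therefore shuffled
and partitioned into four disjoint near-equal parts; each balanced dataset
pairs all positives with one part (roughly 1:2). Each dataset is split
4/5 train : 1/5 test per class. On the training split, features are ranked
by mRMR, and IFS evaluates the nested prefixes S_1 ⊂ S_2 ⊂ ... of the
ranked list under stratified 10-fold cross-validation with a fresh
10-tree forest per fold; the optimal prefix is the smallest k attaining
the maximum cross-validated MCC. Ties between window lengths resolve to
the larger window.

Classification is by majority vote of the 10 trees; the positive-vote
fraction (11 possible values) is the ROC score. A 5-5 tie resolves to
negative -- conservative for a rare-positive screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .features import FeatureCatalog, FeatureMatrix
from .metrics import MetricSet, confusion, mean_metrics, metric_set
from .mrmr import MRMRRanking, discretize, mrmr_rank
from .windowing import PeptideWindow


# ---------------------------------------------------------------------------
# dataset construction


@dataclass
class DatasetBundle:
    """Balanced datasets: every positive plus one disjoint negative part."""

    datasets: list[list[PeptideWindow]]

    def __len__(self) -> int:
        return len(self.datasets)

    def sizes(self) -> list[int]:
        return [len(d) for d in self.datasets]


def build_datasets(
    windows: Sequence[PeptideWindow], parts: int = 4, seed: int = 0
) -> DatasetBundle:
    """Split negatives into ``parts`` disjoint near-equal parts and pair
    each with all positives.

    Negatives are shuffled with a seeded generator, then cut contiguously;
    part sizes differ by at most one (larger parts first). Within each
    dataset the original window order is preserved.
    """
    if parts < 2:
        raise ValueError(f"parts must be >= 2, got {parts}")
    positives = [x for x in windows if x.is_positive]
    neg_idx = [i for i, x in enumerate(windows) if not x.is_positive]
    if len(neg_idx) < parts:
        raise ValueError(
            f"cannot split {len(neg_idx)} negatives into {parts} parts"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(len(neg_idx))
    base, rem = divmod(len(neg_idx), parts)
    datasets = []
    start = 0
    for p in range(parts):
        size = base + (1 if p < rem else 0)
        chosen = sorted(neg_idx[shuffled[i]] for i in range(start, start + size))
        start += size
        negatives = [windows[i] for i in chosen]
        merged = positives + negatives
        merged.sort(key=lambda x: (x.protein_id, x.center_pos))
        datasets.append(merged)
    return DatasetBundle(datasets=datasets)


@dataclass(frozen=True)
class SplitIndices:
    """Stratified train/test index sets over one dataset."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def split_train_test(
    labels: Sequence[int] | Sequence[str] | Sequence[PeptideWindow],
    fraction: float = 0.8,
    seed: int = 0,
) -> SplitIndices:
    """Seeded stratified split: ceil(fraction * n) of each class to train.

    Accepts 0/1 labels, "positive"/"negative" strings, or windows.
    """
    y = _as_binary_labels(labels)
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} has {len(idx)} member(s); cannot split"
            )
        perm = rng.permutation(len(idx))
        n_train = int(np.ceil(fraction * len(idx)))
        train.extend(idx[perm[:n_train]])
        test.extend(idx[perm[n_train:]])
    return SplitIndices(train=tuple(sorted(train)), test=tuple(sorted(test)), seed=seed)


def _as_binary_labels(labels) -> np.ndarray:
    items = list(labels)
    if items and isinstance(items[0], PeptideWindow):
        return np.array([1 if x.is_positive else 0 for x in items])
    if items and isinstance(items[0], str):
        return np.array([1 if s == "positive" else 0 for s in items])
    return np.asarray(items, dtype=int)


# ---------------------------------------------------------------------------
# the 10-tree vote forest


class VoteForestClassifier(ClassifierMixin, BaseEstimator):
    """Small random forest classifying by majority vote of its trees.

    A thin wrapper around :class:`sklearn.ensemble.RandomForestClassifier`
    (default hyperparameters apart from the tree count) that classifies by
    counting tree votes rather than averaging leaf probabilities. The
    positive-vote fraction, quantized to multiples of 1/n_trees, is the
    ranking score; an exact half-half vote resolves to the negative class.

    Parameters
    ----------
    n_trees : int, default 10
    random_state : int or None
    """

    def __init__(self, n_trees: int = 10, random_state: int | None = None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        )
        self.forest_.fit(X, y)
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class (label 1)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        votes = np.zeros(X.shape[0])
        for tree in self.forest_.estimators_:
            votes += (tree.predict(X) == 1).astype(float)
        return votes / len(self.forest_.estimators_)

    def predict(self, X) -> np.ndarray:
        # strictly more than half the votes -> positive; ties are negative
        return (self.vote_fraction(X) > 0.5).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        frac = self.vote_fraction(X)
        return np.column_stack([1 - frac, frac])


# ---------------------------------------------------------------------------
# incremental feature selection


@dataclass
class IFSCurve:
    """Cross-validated metrics for each mRMR prefix size k."""

    ks: np.ndarray
    metrics: list[MetricSet]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "sn": [m.sn for m in self.metrics],
                "sp": [m.sp for m in self.metrics],
                "ac": [m.ac for m in self.metrics],
                "mcc": [m.mcc for m in self.metrics],
            }
        )

    def mcc(self) -> np.ndarray:
        return np.array([m.mcc for m in self.metrics])


def run_ifs(
    X: np.ndarray,
    y: np.ndarray,
    ranking: MRMRRanking | np.ndarray,
    folds: int = 10,
    trees: int = 10,
    seed: int = 0,
    max_k: int | None = None,
) -> IFSCurve:
    """Evaluate nested mRMR prefixes by stratified k-fold cross-validation.

    For each prefix size k the first k ranked features are kept, a fresh
    ``trees``-tree forest is fit per fold, and fold metrics are averaged.
    The same fold partition is reused across every k so the curve is
    comparable point to point. ``max_k`` truncates the scan (the full
    curve has one point per catalog feature).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    order = ranking.mrmr if isinstance(ranking, MRMRRanking) else np.asarray(ranking)
    if len(order) != X.shape[1]:
        raise ValueError("ranking does not cover the feature matrix")
    n_pos = int(y.sum())
    if n_pos < folds:
        raise ValueError(
            f"{n_pos} positives cannot stratify {folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_splits = list(skf.split(X, y))
    kmax = len(order) if max_k is None else min(max_k, len(order))
    ks = np.arange(1, kmax + 1)
    metrics: list[MetricSet] = []
    for k in ks:
        cols = order[:k]
        fold_metrics = []
        for f, (tr, te) in enumerate(fold_splits):
            model = VoteForestClassifier(n_trees=trees, random_state=seed + f)
            model.fit(X[np.ix_(tr, cols)], y[tr])
            pred = model.predict(X[np.ix_(te, cols)])
            fold_metrics.append(metric_set(confusion(y[te], pred)))
        metrics.append(mean_metrics(fold_metrics))
    return IFSCurve(ks=ks, metrics=metrics)


def select_optimal(curve: IFSCurve) -> int:
    """Smallest prefix size k attaining the curve's maximum MCC."""
    mccs = curve.mcc()
    if len(mccs) == 0:
        raise ValueError("empty IFS curve")
    return int(curve.ks[int(np.argmax(mccs))])


def select_window(average_mcc: dict[int, float]) -> int:
    """Window length with the highest average MCC; ties pick the larger."""
    if not average_mcc:
        raise ValueError("no window candidates")
    return max(average_mcc.items(), key=lambda kv: (kv[1], kv[0]))[0]


# ---------------------------------------------------------------------------
# final model


@dataclass
class ModelSpec:
    """A trained final model: selected features plus the fitted forest."""

    window_length: int
    feature_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    classifier: VoteForestClassifier
    seed: int


def train_final(
    matrix: FeatureMatrix,
    selected: Sequence[int] | Sequence[str],
    trees: int = 10,
    seed: int = 0,
) -> ModelSpec:
    """Train one ``trees``-tree forest on the selected feature columns."""
    if len(selected) == 0:
        raise ValueError("empty feature selection")
    if selected and isinstance(list(selected)[0], str):
        idx = tuple(matrix.catalog.index_of(n) for n in selected)
    else:
        idx = tuple(int(i) for i in selected)
    clf = VoteForestClassifier(n_trees=trees, random_state=seed)
    clf.fit(matrix.values[:, idx], matrix.labels)
    return ModelSpec(
        window_length=2 * _catalog_w(matrix.catalog) + 1,
        feature_indices=idx,
        feature_names=tuple(matrix.catalog[i].name for i in idx),
        classifier=clf,
        seed=seed,
    )


def _catalog_w(catalog: FeatureCatalog) -> int:
    return (len(catalog) - 26) // 64


def predict(model: ModelSpec, matrix: FeatureMatrix) -> pd.DataFrame:
    """Classify samples; returns sample id, vote-fraction score, and class.

    The matrix may carry a superset of the model's features (matched by
    name); a missing feature column raises and names it.
    """
    names = matrix.catalog.names()
    cols = []
    for fname in model.feature_names:
        if fname not in names:
            raise ValueError(f"feature column {fname!r} missing from matrix")
        cols.append(names.index(fname))
    X = matrix.values[:, cols]
    score = model.classifier.vote_fraction(X)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "score": score,
            "predicted": (score > 0.5).astype(int),
        }
    )


class IncrementalFeatureClassifier(ClassifierMixin, BaseEstimator):
    """mRMR ranking + IFS + 10-tree vote forest as one sklearn estimator.

    ``fit`` discretizes the training matrix, ranks features by greedy mRMR,
    cross-validates every ranked prefix, keeps the smallest prefix with the
    maximum cross-validated MCC, and trains the final vote forest on it.

    Parameters
    ----------
    folds, trees : int
        Cross-validation folds and forest size.
    max_k : int or None
        Truncate the IFS scan (None scans the full catalog).
    random_state : int

    Attributes
    ----------
    ranking_ : MRMRRanking
    ifs_curve_ : IFSCurve
    k_ : int                 optimal prefix size
    support_ : bool mask of selected features
    estimator_ : fitted VoteForestClassifier
    """

    def __init__(
        self,
        folds: int = 10,
        trees: int = 10,
        max_k: int | None = None,
        random_state: int = 0,
    ):
        self.folds = folds
        self.trees = trees
        self.max_k = max_k
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        disc = discretize(X)
        n_rounds = self.max_k if self.max_k is not None else None
        self.ranking_ = mrmr_rank(disc, y, n_rounds=n_rounds)
        self.ifs_curve_ = run_ifs(
            X,
            y,
            self.ranking_,
            folds=self.folds,
            trees=self.trees,
            seed=self.random_state,
            max_k=self.max_k,
        )
        self.k_ = select_optimal(self.ifs_curve_)
        self.selected_ = np.asarray(self.ranking_.mrmr[: self.k_])
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_] = True
        self.estimator_ = VoteForestClassifier(
            n_trees=self.trees, random_state=self.random_state
        )
        self.estimator_.fit(X[:, self.selected_], y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict(X[:, self.selected_])

    def vote_fraction(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.vote_fraction(X[:, self.selected_])
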