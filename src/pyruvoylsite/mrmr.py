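"""Maximum-Relevance / minimum-Redundancy-Maximum-Relevance feature ranking.

Relevance of a feature f is its mutual information with the class,
D(f) = I(f; c); redundancy against an already-selected set S is the mean
pairwise mutual information R(f) = (1/|S|) * sum_{s in S} I(f; s). The
mRMR ranking is greedy: each round selects argmax_f [D(f) - R(f)] among
the remaining candidates, for as many rounds as there are features. Round
one has an empty selected set (R = 0), so the first mRMR pick is always
the MaxRel top feature.

Mutual information is the plug-in (maximum-likelihood) estimate in bits;
zero joint cells contribute 0 and no pseudo-counts are added. Continuous
features are discretized into three levels at mean +/- one standard
deviation (the convention of the original mRMR program); features with at
most three distinct values pass through as categorical codes, so binary
one-hot features are untouched. The ranking itself is invariant to the
logarithm base, since a base change rescales D and R equally.

Ties at any argmax break toward the lower catalog index, making runs
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass
class DiscretizedMatrix:
    """Integer-coded feature grid plus the number of levels per feature."""

    codes: np.ndarray  # (n_samples, n_features) small non-negative ints
    n_levels: np.ndarray  # (n_features,) number of distinct codes

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


@dataclass
class MRMRRanking:
    """MaxRel and mRMR orderings of the catalog.

    Both are permutations of ``range(n_features)``; ``mrmr[r - 1]`` is the
    feature selected at round r. ``relevance[j]`` is I(feature_j; class)
    in bits.
    """

    maxrel: np.ndarray
    mrmr: np.ndarray
    relevance: np.ndarray

    def round_of(self, feature_index: int) -> int:
        """1-based mRMR round at which a feature was selected."""
        return int(np.flatnonzero(self.mrmr == feature_index)[0]) + 1


def _encode_column(x: np.ndarray) -> tuple[np.ndarray, int]:
    values = np.unique(x)
    if len(values) <= 3:
        codes = np.searchsorted(values, x)
        return codes.astype(np.int64), len(values)
    mu, sigma = x.mean(), x.std()
    codes = np.ones(len(x), dtype=np.int64)
    codes[x < mu - sigma] = 0
    codes[x > mu + sigma] = 2
    return codes, 3


def discretize(values: np.ndarray) -> DiscretizedMatrix:
    """Discretize a feature grid for mutual-information estimation.

    Features with more than three distinct values are binned into
    ``(-inf, mu - sigma)``, ``[mu - sigma, mu + sigma]``, ``(mu + sigma, inf)``;
    others are passed through as categorical codes (a constant feature
    keeps a single code and has zero MI with everything).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected a non-empty 2-D feature grid")
    codes = np.empty(values.shape, dtype=np.int64)
    n_levels = np.empty(values.shape[1], dtype=np.int64)
    for j in range(values.shape[1]):
        codes[:, j], n_levels[j] = _encode_column(values[:, j])
    return DiscretizedMatrix(codes=codes, n_levels=n_levels)


def _codes_of(x: np.ndarray) -> tuple[np.ndarray, int]:
    values, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes.astype(np.int64), len(values)


def _mi_from_codes(x: np.ndarray, nx: int, y: np.ndarray, ny: int) -> float:
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Accepts arbitrary discrete values (relabeling-invariant); returns a
    non-negative, symmetric estimate. Raises on length mismatch.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D vectors")
    cx, nx = _codes_of(x)
    cy, ny = _codes_of(y)
    return _mi_from_codes(cx, nx, cy, ny)


def _relevance(matrix: DiscretizedMatrix, cy: np.ndarray, ny: int) -> np.ndarray:
    return np.array(
        [
            _mi_from_codes(matrix.codes[:, j], int(matrix.n_levels[j]), cy, ny)
            for j in range(matrix.n_features)
        ]
    )


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, int]:
    cy, ny = _codes_of(labels)
    if ny < 2:
        raise ValueError("labels contain a single class; ranking is undefined")
    return cy, ny


def maxrel_rank(matrix: DiscretizedMatrix, labels) -> np.ndarray:
    """Rank features by relevance D = I(f; class), descending.

    Ties break toward the lower catalog index (stable sort on -D).
    """
    cy, ny = _check_labels(np.asarray(labels))
    D = _relevance(matrix, cy, ny)
    return np.argsort(-D, kind="stable")


def mrmr_rank(
    matrix: DiscretizedMatrix, labels, n_rounds: int | None = None
) -> MRMRRanking:
    """Greedy mRMR ranking of all features (or the first ``n_rounds``).

    Each round selects the remaining feature maximizing D(f) - R(f), with
    R(f) the mean MI between f and the features already selected. When
    ``n_rounds`` is smaller than the catalog, the unreached tail is
    appended in MaxRel order so the result remains a full permutation.
    """
    cy, ny = _check_labels(np.asarray(labels))
    p = matrix.n_features
    D = _relevance(matrix, cy, ny)
    maxrel = np.argsort(-D, kind="stable")
    rounds = p if n_rounds is None else min(n_rounds, p)

    selected: list[int] = []
    remaining = np.ones(p, dtype=bool)
    mi_sum = np.zeros(p)  # sum of MI(f, s) over selected s, per candidate f
    for r in range(rounds):
        if r == 0:
            score = D.copy()
        else:
            score = D - mi_sum / len(selected)
        score[~remaining] = -np.inf
        best = int(np.argmax(score))  # argmax takes the first (lowest index) tie
        selected.append(best)
        remaining[best] = False
        cb, nb = matrix.codes[:, best], int(matrix.n_levels[best])
        for j in np.flatnonzero(remaining):
            mi_sum[j] += _mi_from_codes(
                matrix.codes[:, j], int(matrix.n_levels[j]), cb, nb
            )
    if len(selected) < p:
        tail = [j for j in maxrel if remaining[j]]
        selected.extend(tail)
    return MRMRRanking(maxrel=maxrel, mrmr=np.array(selected), relevance=D)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """mRMR feature selection as an sklearn transformer.

    Fitting discretizes the input, ranks every feature by MaxRel and by
    greedy mRMR, and exposes the first ``n_features`` of the mRMR ranking
    as the support mask.

    Parameters
    ----------
    n_features : int or None
        Number of top-ranked features to keep; ``None`` keeps all.
    n_rounds : int or None
        Number of greedy rounds to run; ``None`` ranks the full catalog.

    Attributes
    ----------
    ranking_ : MRMRRanking
    relevance_ : (n_features_in_,) array of I(f; class) in bits.
    """

    def __init__(self, n_features: int | None = None, n_rounds: int | None = None):
        self.n_features = n_features
        self.n_rounds = n_rounds

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        disc = discretize(X)
        self.ranking_ = mrmr_rank(disc, y, n_rounds=self.n_rounds)
        self.relevance_ = self.ranking_.relevance
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        k = self.n_features_in_ if self.n_features is None else self.n_features
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_.mrmr[:k]] = True
        return mask
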