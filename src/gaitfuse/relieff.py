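"""Multi-class ReliefF feature weighting and threshold selection.

ReliefF scores each feature by how well it separates instances from their
nearest neighbors of *other* classes (misses) relative to how much it varies
among nearest neighbors of the *same* class (hits).  For each sampled
instance S the weight of feature N is updated as

    W(N) <- W(N) - (1/(m k)) sum_i diff(N, S, H_i)
                 + (1/(m k)) sum_{C != class(S)} P(C)/(1 - P(class(S)))
                                  sum_j diff(N, S, M_j(C))

where H_i are the k nearest same-class hits, M_j(C) the k nearest misses in
class C, P(C) the class priors, and for continuous features

    diff(N, a, b) = |a_N - b_N| / (max_N - min_N)

(0/1 equality for discrete features; constant features have diff 0).  With
max-min normalized features every |W(N)| <= 1.  Features with weight below
the selection threshold (0.1 by default) are discarded.

Neighbor search runs on per-feature max-min normalized values so the
Euclidean metric and diff agree; ties are broken by lowest row index and the
sampled instance is never its own hit, making the result deterministic for
a fixed seed (the default m = all instances needs no sampling at all).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError


class ReliefF(TransformerMixin, BaseEstimator):
    """ReliefF feature weighting with threshold selection.

    Parameters
    ----------
    n_neighbors : int
        k, nearest hits/misses per class (per-class size must exceed k).
    n_samples : int or None
        m, number of sampled instances.  None (default) uses every instance
        exactly once, which is fully deterministic; an integer samples m
        instances without replacement using `random_state`.
    threshold : float
        Features with fitted weight below this value are dropped by
        :meth:`transform`.
    discrete : bool array of shape (n_features,), optional
        Marks features scored with the 0/1 equality diff instead of the
        range-normalized absolute difference.

    Attributes
    ----------
    weights_ : ndarray, per-feature ReliefF weight W(N)
    priors_ : dict, class -> P(C)
    support_ : bool mask of surviving features (weights_ >= threshold)
    """

    def __init__(self, n_neighbors=10, n_samples=None, threshold=0.1,
                 random_state=0, discrete=None):
        self.n_neighbors = n_neighbors
        self.n_samples = n_samples
        self.threshold = threshold
        self.random_state = random_state
        self.discrete = discrete

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        n, p = X.shape
        k = int(self.n_neighbors)
        if k < 1:
            raise ValueError("n_neighbors must be >= 1")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("ReliefF needs at least two classes")
        for cls, cnt in zip(classes, counts):
            if cnt <= k:
                raise ValueError(
                    f"class {cls!r} has {cnt} members but k={k} neighbors "
                    f"are requested; reduce n_neighbors to < {cnt} or "
                    "provide more samples")

        priors = counts / n
        self.classes_ = classes
        self.priors_ = dict(zip(classes.tolist(), priors.tolist()))
        self.n_features_in_ = p

        discrete = (np.zeros(p, dtype=bool) if self.discrete is None
                    else np.asarray(self.discrete, dtype=bool))

        # range normalization; constant (zero-range) features get diff 0
        rng_span = X.max(axis=0) - X.min(axis=0)
        nonconst = rng_span > 0
        Z = np.zeros_like(X)
        Z[:, nonconst] = ((X[:, nonconst] - X[:, nonconst].min(axis=0))
                          / rng_span[nonconst])

        if self.n_samples is None:
            sample_idx = np.arange(n)
        else:
            m = int(self.n_samples)
            if m < 1:
                raise ValueError("n_samples must be >= 1")
            rng = np.random.default_rng(self.random_state)
            sample_idx = rng.choice(n, size=min(m, n), replace=False)
        m = len(sample_idx)

        cls_rows = {c: np.flatnonzero(y == c) for c in classes}
        W = np.zeros(p)
        for s in sample_idx:
            zs = Z[s]
            # per-feature diffs of s against everyone (n, p)
            diffs = np.abs(Z - zs[None, :])
            diffs[:, discrete] = (X[:, discrete] != X[s, discrete]).astype(float)
            dist = np.sqrt(np.sum(diffs**2, axis=1))
            for c in classes:
                rows = cls_rows[c]
                if c == y[s]:
                    rows = rows[rows != s]  # self is never its own hit
                # k nearest, ties by lowest row index (stable sort on dist)
                order = rows[np.argsort(dist[rows], kind="stable")[:k]]
                contrib = diffs[order].sum(axis=0)
                if c == y[s]:
                    W -= contrib / (m * k)
                else:
                    factor = self.priors_[c] / (1.0 - self.priors_[y[s]])
                    W += factor * contrib / (m * k)

        self.weights_ = W
        self.support_ = W >= self.threshold
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise NotFittedError("ReliefF has not been fitted")

    def get_support(self, indices=False):
        self._check_fitted()
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        """Keep exactly the columns whose weight reached the threshold."""
        self._check_fitted()
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than fit")
        n_keep = int(self.support_.sum())
        if n_keep == 0:
            raise ValueError(
                f"no features reach weight threshold {self.threshold}; "
                f"max weight is {self.weights_.max():.4f} — lower the "
                "threshold")
        if n_keep < 3:
            import warnings

            warnings.warn(f"only {n_keep} features survive the ReliefF "
                          f"threshold {self.threshold}", stacklevel=2)
        return X[:, self.support_]


def diff(a: float, b: float, feature_range: float,
         discrete: bool = False) -> float:
    """Single-feature diff: range-normalized absolute difference for
    continuous features (0 for zero-range features), 0/1 equality for
    discrete ones."""
    if discrete:
        return 0.0 if a == b else 1.0
    if feature_range <= 0:
        return 0.0
    return abs(a - b) / feature_range


def relieff_weights(X, y, n_neighbors=10, n_samples=None, threshold=0.1,
                    random_state=0) -> ReliefF:
    """Functional wrapper: fit and return the ReliefF estimator."""
    return ReliefF(n_neighbors=n_neighbors, n_samples=n_samples,
                   threshold=threshold, random_state=random_state).fit(X, y)


def select(fm, selector: ReliefF):
    """Apply a fitted selector to a FeatureMatrix, keeping names aligned."""
    from .features import FeatureMatrix

    vals = selector.transform(fm.values)
    names = [n for n, keep in zip(fm.feature_names, selector.support_) if keep]
    return FeatureMatrix(vals, names, fm.labels)


def save_weights(fm_names, selector: ReliefF, path) -> None:
    pd.DataFrame({"feature": fm_names, "weight": selector.weights_}).to_csv(
        path, index=False)
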