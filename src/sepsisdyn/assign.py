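"""Phenotype transfer by k-nearest neighbours under Gaussian similarity.

Phenotypes are derived once, on the derivation cohort's 3 h
representations; membership for new patients — the 6 h snapshot and any
external-validation cohort — is assigned by k-nearest neighbours using the
same Gaussian similarity metric, with the bandwidth frozen at fit time.
Because the Gaussian kernel decreases strictly with distance, the
neighbour sets coincide with Euclidean nearest neighbours; the kernel
enters through the similarity-weighted vote and the confidence proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_X_y

from .cluster import SimilarityConfig, _resolve_sigma

__all__ = ["GaussianKNNClassifier", "knn_assign", "compare_profiles"]


class GaussianKNNClassifier(BaseEstimator, ClassifierMixin):
    """Similarity-weighted kNN vote under a frozen Gaussian kernel.

    Parameters
    ----------
    n_neighbors : int, default 15
        Neighbourhood size. The value is not pinned by any external
        constraint; 15 is a common default balancing noise and locality.
    sigma : float, "median-knn" or "median-heuristic", default "median-knn"
        Kernel bandwidth rule, resolved once on the reference data at
        ``fit`` and frozen thereafter (the same metric used during
        phenotype derivation).

    Votes are weighted by similarity; ties break toward the larger summed
    similarity and then the lower label index, so prediction is fully
    deterministic.

    Attributes
    ----------
    X_ : ndarray            reference representations
    y_ : ndarray            reference labels (1..k)
    sigma_ : float          frozen bandwidth
    classes_ : ndarray
    """

    def __init__(self, n_neighbors: int = 15,
                 sigma: float | str = "median-knn", knn_k: int = 7):
        self.n_neighbors = n_neighbors
        self.sigma = sigma
        self.knn_k = knn_k

    def fit(self, X, y) -> "GaussianKNNClassifier":
        X, y = check_X_y(X, y)
        if len(X) == 0:
            raise ValueError("reference set is empty")
        if self.n_neighbors < 1 or self.n_neighbors > len(X):
            raise ValueError("n_neighbors must be in [1, n_reference]")
        self.X_ = X
        self.y_ = y.astype(np.int64)
        self.classes_ = np.unique(self.y_)
        D = squareform(pdist(X)) if len(X) > 1 else np.zeros((1, 1))
        self.sigma_ = _resolve_sigma(D, self.sigma, self.knn_k)
        return self

    def _similarities(self, X) -> np.ndarray:
        d2 = cdist(X, self.X_, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.sigma_ ** 2))

    def predict(self, X, return_confidence: bool = False):
        X = check_array(X)
        if not hasattr(self, "X_"):
            raise RuntimeError("classifier is not fitted")
        if X.shape[1] != self.X_.shape[1]:
            raise ValueError("query width differs from reference width")
        S = self._similarities(X)
        k = self.n_neighbors
        # deterministic neighbour selection: sort by (-similarity, index)
        order = np.lexsort((np.arange(S.shape[1])[None, :].repeat(len(S), 0), -S),
                           axis=1)[:, :k]
        labels = np.empty(len(X), dtype=np.int64)
        confidence = np.empty(len(X))
        max_label = int(self.y_.max())
        for i in range(len(X)):
            nb = order[i]
            votes = np.zeros(max_label + 1)
            np.add.at(votes, self.y_[nb], S[i, nb])
            best = votes.max()
            labels[i] = int(np.flatnonzero(votes == best)[0])  # lowest label
            confidence[i] = S[i, nb].mean()
        if return_confidence:
            return labels, confidence
        return labels


def knn_assign(reference_X, reference_labels, query_X, n_neighbors: int = 15,
               sigma: float | str = "median-knn") -> np.ndarray:
    """Functional wrapper: fit on the reference, label the query rows."""
    clf = GaussianKNNClassifier(n_neighbors=n_neighbors, sigma=sigma)
    return clf.fit(reference_X, reference_labels).predict(query_X)


# --------------------------------------------------------------------------


def compare_profiles(derivation: pd.DataFrame,
                     validation: pd.DataFrame) -> dict:
    """Concordance between derivation and validation phenotype profiles.

    Both inputs are tables indexed by phenotype with one column per
    summarized quantity (variable means, outcome rates). Returns
    standardized differences per phenotype x column (difference over the
    pooled across-phenotype SD of the derivation column) and, for each
    column, the Spearman rank agreement of the phenotype ordering.
    """
    if not derivation.index.equals(validation.index):
        raise ValueError("profiles must cover the same phenotypes (same k)")
    if list(derivation.columns) != list(validation.columns):
        raise ValueError("profiles must cover the same variable set")
    sd = derivation.std(axis=0, ddof=0).replace(0.0, np.nan)
    std_diff = (validation - derivation) / sd
    std_diff = std_diff.fillna(0.0)

    rank_agreement = {}
    for col in derivation.columns:
        a = rankdata(derivation[col])
        b = rankdata(validation[col])
        n = len(a)
        if n < 2 or np.allclose(a, a[0]) or np.allclose(b, b[0]):
            rho = np.nan
        else:
            rho = float(np.corrcoef(a, b)[0, 1])
        rank_agreement[col] = rho
    return {
        "standardized_differences": std_diff,
        "rank_agreement": pd.Series(rank_agreement),
        "max_abs_std_diff": float(std_diff.abs().to_numpy().max()),
    }
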