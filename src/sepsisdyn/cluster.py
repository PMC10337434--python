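"""Consensus spectral clustering with Gaussian similarity.

Spectral clustering represents patients as nodes of a weighted graph whose
edge weights are Gaussian similarities ``W_ij = exp(-||x_i - x_j||^2 /
(2 sigma^2))``; clustering runs k-means on the row-normalized eigenvectors
of the k smallest eigenvalues of the symmetric normalized Laplacian
``L = I - D^{-1/2} W D^{-1/2}`` (the Ng-Jordan-Weiss construction). To
assess stability and select the number of clusters, the algorithm runs in
a Monti-style consensus loop: R random subsamples (fraction p, without
replacement) are clustered for every candidate k, and the consensus matrix
``M(k)_ij`` records the fraction of co-sampled runs in which i and j were
co-clustered. The empirical CDF of consensus entries, its area A(k) and
the relative area increments delta(k) drive the choice of k: the selected
k is the smallest in range whose next increment falls below a threshold
(stability has plateaued). Final labels come from average-linkage
hierarchical clustering of the consensus distance 1 - M at the chosen k,
so the reported partition is the consensus object itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array

__all__ = [
    "SimilarityConfig",
    "ConsensusConfig",
    "ConsensusResult",
    "gaussian_similarity",
    "spectral_cluster",
    "consensus_cluster",
    "ConsensusSpectralClustering",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Gaussian-kernel settings.

    sigma : positive float, "median-knn" or "median-heuristic"
        Kernel bandwidth. ``"median-knn"`` (default) is a local-scale rule:
        the median distance to the ``knn_k``-th nearest neighbour across
        points — bandwidths on the within-cluster scale keep the affinity
        graph local, which is what makes consensus stability informative.
        ``"median-heuristic"`` is the classical global rule (median pairwise
        distance). Both are evaluated on the data at hand (per subsample
        inside the consensus loop). Degenerate all-identical data fall back
        to sigma = 1 with a warning.
    n_neighbors : int or None
        Optional symmetrized m-nearest-neighbor sparsification of W.
    knn_k : int
        Neighbour order used by the "median-knn" rule.
    """

    sigma: float | str = "median-knn"
    n_neighbors: int | None = None
    knn_k: int = 7

    def __post_init__(self) -> None:
        if not isinstance(self.sigma, str) and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus-loop settings (Monti-style resampling).

    ``selection`` picks the k-selection rule applied to the consensus CDFs:

    * ``"pac"`` (default): the proportion of ambiguous clustering
      PAC(k) = CDF(0.9) - CDF(0.1) measures how many pairs are neither
      reliably together nor reliably apart; the chosen k is the largest
      whose PAC lies within ``pac_tie_eps`` of the minimum, and if even
      the best PAC exceeds ``pac_unstable`` (no k clusters stably) the
      floor of the search range is returned.

    Any k whose consensus partition contains a cluster smaller than
    ``min_cluster_fraction`` of the cohort is disqualified from selection
    (a stably separating outlier clump is not a phenotype); if every k is
    disqualified the guard is ignored.
    * ``"delta"``: the forward delta-area rule — smallest k whose next
      relative area increment falls below ``delta_threshold`` (last k if
      none does). Fragile when cluster prevalences are very unequal: the
      area gained by splitting a dominant cluster can exceed the gain from
      resolving a small true cluster.
    """

    k_range: tuple[int, int] = (2, 6)
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    delta_threshold: float = 0.05
    selection: str = "pac"
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    pac_tie_eps: float = 0.005
    pac_unstable: float = 0.25
    min_cluster_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must satisfy 2 <= kmin <= kmax")
        if self.n_resamples < 2:
            raise ValueError("need at least 2 resamples")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction in (0, 1]")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")
        if self.selection not in ("pac", "delta"):
            raise ValueError("selection must be 'pac' or 'delta'")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF summaries and the selected partition."""

    k_values: list[int]
    consensus: dict                       # k -> (n, n) matrix in [0, 1]
    cosample_counts: np.ndarray           # (n, n) integer co-sampling tallies
    cdf_grid: np.ndarray
    cdfs: dict                            # k -> CDF values on cdf_grid
    areas: dict                           # k -> A(k)
    deltas: dict                          # k -> delta(k)
    pac: dict                             # k -> PAC(k)
    chosen_k: int
    labels: np.ndarray                    # 1..chosen_k
    labels_per_k: dict = field(default_factory=dict)
    never_cosampled: int = 0
    runs: list = field(default_factory=list)  # optional per-run logs


# --------------------------------------------------------------------------


def _resolve_sigma(dist_matrix: np.ndarray, sigma, knn_k: int = 7) -> float:
    """Bandwidth from a full (n, n) distance matrix under the given rule."""
    if not isinstance(sigma, str):
        return float(sigma)
    n = dist_matrix.shape[0]
    if sigma in ("median-heuristic", "median"):
        iu = np.triu_indices(n, k=1)
        med = float(np.median(dist_matrix[iu])) if n > 1 else 0.0
    elif sigma == "median-knn":
        kth = min(max(1, knn_k), n - 1)
        part = np.partition(dist_matrix, kth, axis=1)[:, kth]
        med = float(np.median(part))
    else:
        raise ValueError(f"unknown sigma rule {sigma!r}")
    if med <= 0.0:
        warnings.warn("degenerate pairwise distances; sigma rule undefined, "
                      "falling back to sigma=1")
        return 1.0
    return med


def gaussian_similarity(X: np.ndarray,
                        config: SimilarityConfig | None = None) -> np.ndarray:
    """Dense Gaussian affinity ``W_ij = exp(-||x_i-x_j||^2 / (2 sigma^2))``.

    Symmetric with unit diagonal; optionally sparsified to the symmetrized
    m-nearest-neighbor graph (an edge survives if either endpoint ranks the
    other among its m nearest).
    """
    config = config or SimilarityConfig()
    X = check_array(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    D = squareform(pdist(X))
    sigma = _resolve_sigma(D, config.sigma, config.knn_k)
    W = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(W, 1.0)
    if config.n_neighbors is not None:
        m = int(config.n_neighbors)
        n = W.shape[0]
        keep = np.zeros_like(W, dtype=bool)
        # nearest by similarity, excluding self
        order = np.argsort(-(W - np.eye(n)), axis=1)[:, :m]
        rows = np.repeat(np.arange(n), m)
        keep[rows, order.ravel()] = True
        keep |= keep.T
        W = np.where(keep, W, 0.0)
        np.fill_diagonal(W, 1.0)
    return W


def _spectral_embedding(W: np.ndarray, k_max: int) -> np.ndarray:
    """Eigenvectors of the k_max smallest eigenvalues of the symmetric
    normalized Laplacian (columns ordered by eigenvalue)."""
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    L = np.eye(W.shape[0]) - W * inv_sqrt[:, None] * inv_sqrt[None, :]
    _, vecs = eigh(L, subset_by_index=[0, k_max - 1])
    return vecs


def _row_normalize(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    return U / np.where(norms > 0, norms, 1.0)


def _kmeans_labels(U: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=20, random_state=seed, algorithm="lloyd")
    return km.fit_predict(U)


def spectral_cluster(W: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of an affinity matrix; labels 1..k.

    Zero-degree isolates (possible only under sparsification) are removed
    from the eigenproblem and assigned post hoc the label of their most
    similar non-isolated point.
    """
    W = np.asarray(W, float)
    n = W.shape[0]
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be square and symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        return np.ones(n, dtype=np.int64)

    offdiag = W - np.diag(np.diagonal(W))
    deg = offdiag.sum(axis=1)
    isolated = deg <= 0
    active = ~isolated
    Wa = W[np.ix_(active, active)]
    if active.sum() < k:
        warnings.warn("fewer connected points than clusters; "
                      "assigning by similarity blocks")
        labels = np.ones(n, dtype=np.int64)
        labels[isolated] = 1
        return labels

    U = _spectral_embedding(Wa, k)
    labels_active = _kmeans_labels(_row_normalize(U), k, seed) + 1

    labels = np.empty(n, dtype=np.int64)
    labels[active] = labels_active
    if isolated.any():
        act_idx = np.flatnonzero(active)
        for i in np.flatnonzero(isolated):
            nearest = act_idx[np.argmax(offdiag[i, active])]
            labels[i] = labels[nearest]
    return labels


# --------------------------------------------------------------------------


def _consensus_cdf(M: np.ndarray, grid: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    return np.searchsorted(np.sort(vals), grid, side="right") / vals.size


def consensus_cluster(X: np.ndarray, cc: ConsensusConfig | None = None,
                      sc: SimilarityConfig | None = None,
                      store_runs: bool = False) -> ConsensusResult:
    """Monti consensus loop around spectral clustering; selects k.

    For each of R seeded subsamples (shared across candidate k), spectral
    clustering labels the subsample at every k in range; consensus entries
    are co-clustering counts over co-sampling counts. Pairs never
    co-sampled get consensus 0 and are tallied in ``never_cosampled``.
    A(k) is the trapezoid area under the consensus CDF; delta(2) = A(2) and
    delta(k) = (A(k) - A(k-1)) / A(k-1). The number of clusters is chosen
    from the CDFs by the configured rule (PAC by default; see
    :class:`ConsensusConfig`).
    """
    cc = cc or ConsensusConfig()
    sc = sc or SimilarityConfig()
    X = check_array(X)
    n = X.shape[0]
    k_min, k_max = cc.k_range
    if n < k_max:
        raise ValueError("need at least k_max samples")
    ks = list(range(k_min, k_max + 1))

    rng = np.random.default_rng(cc.seed)
    m = max(k_max, int(round(cc.subsample_fraction * n)))

    # full pairwise squared distances once; subsample blocks are views
    D2 = squareform(pdist(X) ** 2)

    cosample = np.zeros((n, n), dtype=np.int32)
    cocluster = {k: np.zeros((n, n), dtype=np.int32) for k in ks}
    seeds = np.random.SeedSequence(cc.seed).generate_state(cc.n_resamples * len(ks))
    runs = []

    for r in range(cc.n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        block = D2[np.ix_(idx, idx)]
        sigma = _resolve_sigma(np.sqrt(block), sc.sigma, sc.knn_k)
        W = np.exp(-block / (2.0 * sigma ** 2))
        if sc.n_neighbors is not None:
            mm = int(sc.n_neighbors)
            keep = np.zeros_like(W, dtype=bool)
            order = np.argsort(-(W - np.eye(m)), axis=1)[:, :mm]
            keep[np.repeat(np.arange(m), mm), order.ravel()] = True
            keep |= keep.T
            W = np.where(keep, W, 0.0)
            np.fill_diagonal(W, 1.0)

        U_full = _spectral_embedding(W, k_max)
        cosample[np.ix_(idx, idx)] += 1
        run_log = {"indices": idx, "labels": {}} if store_runs else None
        for j, k in enumerate(ks):
            seed = int(seeds[r * len(ks) + j] % (2 ** 31))
            lab = _kmeans_labels(_row_normalize(U_full[:, :k]), k, seed)
            same = (lab[:, None] == lab[None, :])
            cocluster[k][np.ix_(idx, idx)] += same
            if store_runs:
                run_log["labels"][k] = lab + 1
        if store_runs:
            runs.append(run_log)

    never = int((cosample[np.triu_indices(n, k=1)] == 0).sum())
    if never:
        warnings.warn(f"{never} pairs never co-sampled; consensus set to 0")

    grid = np.linspace(0.0, 1.0, 101)
    consensus, cdfs, areas = {}, {}, {}
    denom = np.maximum(cosample, 1)
    for k in ks:
        M = cocluster[k] / denom
        M = np.where(cosample > 0, M, 0.0)
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        cdfs[k] = _consensus_cdf(M, grid)
        areas[k] = float(np.trapezoid(cdfs[k], grid))

    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf

    lo, hi = cc.pac_bounds
    pac = {
        k: float(np.interp(hi, grid, cdfs[k]) - np.interp(lo, grid, cdfs[k]))
        for k in ks
    }

    # final candidate partitions: average linkage on consensus distance
    labels_per_k = {}
    for k in ks:
        dist = 1.0 - consensus[k]
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels_per_k[k] = fcluster(Z, t=k, criterion="maxclust").astype(np.int64)

    min_size = cc.min_cluster_fraction * n
    eligible = [k for k in ks
                if np.bincount(labels_per_k[k]).max(initial=0) > 0
                and np.bincount(labels_per_k[k])[1:].min() >= min_size]
    if not eligible:
        eligible = ks

    if cc.selection == "pac":
        best = min(pac[k] for k in eligible)
        if best > cc.pac_unstable:
            chosen = ks[0]
        else:
            chosen = max(k for k in eligible if pac[k] <= best + cc.pac_tie_eps)
    else:  # forward delta-area rule
        chosen = eligible[-1]
        for i, k in enumerate(eligible[:-1]):
            if deltas[eligible[i + 1]] < cc.delta_threshold:
                chosen = k
                break

    labels = labels_per_k[chosen]

    return ConsensusResult(
        k_values=ks, consensus=consensus, cosample_counts=cosample,
        cdf_grid=grid, cdfs=cdfs, areas=areas, deltas=deltas, pac=pac,
        chosen_k=chosen, labels=labels, labels_per_k=labels_per_k,
        never_cosampled=never, runs=runs,
    )


class ConsensusSpectralClustering(BaseEstimator, ClusterMixin):
    """Estimator facade over :func:`consensus_cluster`.

    Parameters mirror :class:`ConsensusConfig` / :class:`SimilarityConfig`.
    After ``fit``: ``labels_`` (1..n_clusters_), ``n_clusters_``,
    ``result_`` (the full :class:`ConsensusResult`), ``areas_``,
    ``deltas_``.
    """

    def __init__(self, k_range: tuple[int, int] = (2, 6),
                 n_resamples: int = 100, subsample_fraction: float = 0.8,
                 delta_threshold: float = 0.05, selection: str = "pac",
                 sigma: float | str = "median-knn",
                 n_neighbors: int | None = None, random_state: int = 0,
                 store_runs: bool = False):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.delta_threshold = delta_threshold
        self.selection = selection
        self.sigma = sigma
        self.n_neighbors = n_neighbors
        self.random_state = random_state
        self.store_runs = store_runs

    def fit(self, X, y=None) -> "ConsensusSpectralClustering":
        cc = ConsensusConfig(
            k_range=tuple(self.k_range), n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            delta_threshold=self.delta_threshold, selection=self.selection,
            seed=self.random_state,
        )
        sc = SimilarityConfig(sigma=self.sigma, n_neighbors=self.n_neighbors)
        self.result_ = consensus_cluster(X, cc, sc, store_runs=self.store_runs)
        self.labels_ = self.result_.labels
        self.n_clusters_ = self.result_.chosen_k
        self.areas_ = self.result_.areas
        self.deltas_ = self.result_.deltas
        self.pac_ = self.result_.pac
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
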