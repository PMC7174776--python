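"""Hypergraph construction over pair-feature vectors.

Two complementary hyperedge generators are used: a KNN view, where each
vertex spawns a hyperedge containing itself and its k1 nearest neighbours
(weighted by the summed Gaussian affinity of the centroid to its
neighbours), and a K-means view, where each cluster forms one hyperedge and
all hyperedges share an equal weight 1/n_e.  Both are summarised by the
normalised hypergraph Laplacian

    Delta = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}

whose quadratic form tr(P^T X^T Delta X P) penalises label disagreement
within hyperedges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "Hypergraph",
    "HypergraphConfig",
    "gaussian_sigma",
    "pair_affinity",
    "build_knn_hypergraph",
    "build_kmeans_hypergraph",
    "laplacian",
    "omega_regularizer",
]


@dataclass
class HypergraphConfig:
    k1: int = 20          # KNN neighbours per centroid
    k2: int = 100         # number of K-means clusters
    rng_seed: int = 0
    normalize_knn_weights: bool = False
    include_self_affinity: bool = False

    def __post_init__(self) -> None:
        if self.k1 < 1:
            raise ValueError("k1 must be >= 1")
        if self.k2 < 1:
            raise ValueError("k2 must be >= 1")


@dataclass
class Hypergraph:
    """Incidence structure with hyperedge weights, degrees and Laplacian.

    H is the |V| x |E| binary incidence matrix, w the hyperedge weight
    vector; vertex degrees d(v) = sum_e w(e) h(v,e) and hyperedge degrees
    delta(e) = sum_v h(v,e) follow from them.
    """

    H: np.ndarray
    w: np.ndarray
    kind: str
    Dv: np.ndarray = field(init=False)
    De: np.ndarray = field(init=False)
    Delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all((self.H == 0) | (self.H == 1)):
            raise ValueError("incidence matrix must be binary")
        if self.H.shape[1] != self.w.shape[0]:
            raise ValueError("one weight per hyperedge required")
        self.De = self.H.sum(axis=0)
        if np.any(self.De < 1):
            raise ValueError("empty hyperedge (degree 0)")
        self.Dv = self.H @ self.w
        self.Delta = laplacian(self.H, self.w)

    @property
    def n_vertices(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]


def gaussian_sigma(X: np.ndarray) -> float:
    """Mean-dispersion bandwidth: sigma = (1/(n-1)) sum_i ||x_i - xbar||^2."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two feature rows")
    xbar = X.mean(axis=0)
    sigma = float(((X - xbar) ** 2).sum() / (n - 1))
    if sigma == 0:
        raise ValueError("all feature rows identical; Gaussian kernel degenerate")
    return sigma


def pair_affinity(xv: np.ndarray, xu: np.ndarray, sigma: float) -> float:
    """exp(-||xv - xu||^2 / sigma^2)."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    d2 = float(((np.asarray(xv, float) - np.asarray(xu, float)) ** 2).sum())
    return float(np.exp(-d2 / sigma ** 2))


def build_knn_hypergraph(X: np.ndarray, cfg: HypergraphConfig) -> Hypergraph:
    """One hyperedge per vertex: the centroid plus its k1 nearest neighbours.

    Neighbour ties are broken by ascending index.  The hyperedge weight is
    the summed centroid-to-neighbour affinity (self excluded unless
    cfg.include_self_affinity).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if cfg.k1 >= n:
        raise ValueError(f"k1={cfg.k1} must be smaller than the number of vertices ({n})")
    sigma = gaussian_sigma(X)
    d2 = cdist(X, X, metric="sqeuclidean")
    aff = np.exp(-d2 / sigma ** 2)
    H = np.zeros((n, n))
    w = np.zeros(n)
    idx = np.arange(n)
    for v in range(n):
        dv = d2[v].copy()
        dv[v] = -np.inf  # the centroid always belongs to its own edge
        order = np.lexsort((idx, dv))
        members = order[: cfg.k1 + 1]
        H[members, v] = 1.0
        neigh = members[members != v]
        w[v] = aff[v, neigh].sum()
        if cfg.include_self_affinity:
            w[v] += 1.0
    if cfg.normalize_knn_weights:
        w = w / w.sum()
    return Hypergraph(H, w, "knn")


def build_kmeans_hypergraph(X: np.ndarray, cfg: HypergraphConfig) -> Hypergraph:
    """One hyperedge per non-empty K-means cluster, equal weights 1/n_e."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if cfg.k2 > n:
        raise ValueError(f"k2={cfg.k2} exceeds the number of vertices ({n})")
    km = KMeans(
        n_clusters=cfg.k2,
        init="k-means++",
        n_init=10,
        max_iter=300,
        random_state=cfg.rng_seed,
    ).fit(X)
    labels = km.labels_
    clusters = [np.nonzero(labels == c)[0] for c in range(cfg.k2)]
    nonempty = [c for c in clusters if c.size > 0]
    if len(nonempty) < len(clusters):
        warnings.warn(
            f"{len(clusters) - len(nonempty)} empty K-means clusters dropped"
        )
    n_e = len(nonempty)
    H = np.zeros((n, n_e))
    for e, members in enumerate(nonempty):
        H[members, e] = 1.0
    w = np.full(n_e, 1.0 / n_e)
    return Hypergraph(H, w, "kmeans")


def laplacian(H: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Normalised hypergraph Laplacian Delta = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}."""
    H = np.asarray(H, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    dv = H @ w
    de = H.sum(axis=0)
    if np.any(de <= 0):
        raise ValueError("hyperedge with degree 0")
    if np.any(dv <= 0):
        v = int(np.nonzero(dv <= 0)[0][0])
        raise ValueError(f"isolated vertex {v} has degree 0")
    dv_isqrt = 1.0 / np.sqrt(dv)
    theta = (dv_isqrt[:, None] * H) * (w / de) @ H.T * dv_isqrt[None, :]
    delta = np.eye(H.shape[0]) - theta
    return (delta + delta.T) / 2.0


def omega_regularizer(P: np.ndarray, X: np.ndarray, hg: Hypergraph) -> float:
    """Hypergraph Laplacian regulariser tr(P^T X^T Delta X P).

    Equals the explicit half double sum over hyperedges and vertex pairs of
    the degree-normalised projected-label differences.
    """
    XP = np.asarray(X, float) @ np.asarray(P, float)
    return float(np.trace(XP.T @ hg.Delta @ XP))
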