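"""Low-dimensional embedding of the band-power feature matrix.

Isomap: build a k-nearest-neighbor graph on the windowed feature vectors
(k chosen adaptively as the smallest k >= ceil(sqrt(n)) giving a connected
graph), approximate manifold geodesics by graph shortest paths (Dijkstra),
and apply classical multidimensional scaling to the geodesic distance
matrix. A PCA baseline embeds the same features linearly. Embedding
dimensionality is chosen by an automated elbow rule on the eigenvalue
spectrum, and embedding quality is summarized by trustworthiness and
cumulative explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .preprocess import FeatureMatrix

__all__ = [
    "NeighborGraph",
    "Embedding",
    "ElbowResult",
    "pairwise_euclidean",
    "knn_adjacency",
    "select_k",
    "geodesic_distances",
    "classical_mds",
    "pca_embed",
    "isomap_embed",
    "elbow_dimension",
    "trustworthiness",
    "explained_variance",
]


def _as_matrix(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetrized k-NN graph: finite entries are Euclidean distances,
    non-edges are +inf, the diagonal is 0 (self is not a neighbor)."""

    weights: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(
            csr_matrix(np.where(np.isfinite(self.weights), self.weights, 0.0)),
            directed=False,
        )
        return n_comp == 1


@dataclass(frozen=True)
class Embedding:
    """n x d coordinates plus the full eigenvalue spectrum.

    For MDS-based embeddings column j of coords has squared norm equal to
    eigenvalue j. `method` is "isomap" or "pca"; `k_used` is the neighborhood
    size (Isomap only).
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    method: str
    d: int
    k_used: int | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ElbowResult:
    """Outcome of the automated elbow rule."""

    dimension: int
    curvature: float
    clear: bool


def pairwise_euclidean(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances between windows."""
    M = _as_matrix(X)
    if M.shape[0] < 2:
        raise ValueError("need at least two windows for pairwise distances")
    return squareform(pdist(M, metric="euclidean"))


def knn_adjacency(D: np.ndarray, k: int) -> NeighborGraph:
    """OR-symmetrized k-NN graph from a distance matrix.

    An edge (i, j) exists when j is among the k nearest neighbors of i *or*
    vice versa; edge weights copy D. Ties are broken toward the lowest index
    (stable argsort), and a point is never its own neighbor.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    order = np.argsort(D, axis=1, kind="stable")
    is_edge = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nbrs = order[i][order[i] != i][:k]
        is_edge[i, nbrs] = True
    is_edge |= is_edge.T  # OR rule
    weights = np.where(is_edge, D, np.inf)
    np.fill_diagonal(weights, 0.0)
    return NeighborGraph(weights=weights, k=k)


def select_k(D: np.ndarray) -> int:
    """Smallest k >= ceil(sqrt(n)) whose OR-symmetrized k-NN graph is connected.

    Starts from k0 = ceil(sqrt(n)) and increments by one until the graph is
    fully connected; k = n - 1 (complete graph) always terminates the search.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two points to select k")
    k = int(np.ceil(np.sqrt(n)))
    k = min(max(k, 1), n - 1)
    while True:
        if knn_adjacency(D, k).is_connected():
            return k
        k += 1


def geodesic_distances(graph: NeighborGraph) -> np.ndarray:
    """All-pairs shortest-path (geodesic) distances on the neighbor graph."""
    finite = np.where(np.isfinite(graph.weights), graph.weights, 0.0)
    G = dijkstra(csr_matrix(finite), directed=False)
    if not np.all(np.isfinite(G)):
        raise ValueError(
            "neighbor graph is disconnected; increase k until it is connected"
        )
    return G


def classical_mds(G: np.ndarray, d: int) -> Embedding:
    """Classical MDS of a distance matrix.

    Double-centers the squared distances, B = -1/2 H G^2 H with
    H = I - (1/n) 11^T, eigendecomposes B, and forms coordinates from the d
    largest eigenvalues: Y = V_d Lambda_d^{1/2}. Negative eigenvalues (the
    geodesic matrix is generally non-Euclidean) are reported in the spectrum
    but excluded from the coordinates. Eigenvector signs are fixed so each
    column's largest-magnitude component is positive.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if d < 1:
        raise ValueError("d must be >= 1")
    H = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * H @ (G**2) @ H
    B = 0.5 * (B + B.T)  # guard against floating-point asymmetry
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    n_pos = int(np.sum(eigvals > 0))
    if d > n_pos:
        raise ValueError(
            f"d={d} exceeds the {n_pos} positive eigenvalues; max usable d is {n_pos}"
        )
    V = eigvecs[:, :d]
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    V = V * signs
    coords = V * np.sqrt(eigvals[:d])
    return Embedding(coords=coords, eigenvalues=eigvals, method="mds", d=d)


def isomap_embed(
    X: FeatureMatrix | np.ndarray, d: int, k: int | None = None
) -> Embedding:
    """Isomap: k-NN graph -> geodesic distances -> classical MDS.

    If k is None the smallest connectivity-preserving k from `select_k` is
    used.
    """
    D = pairwise_euclidean(X)
    if k is None:
        k = select_k(D)
    graph = knn_adjacency(D, k)
    G = geodesic_distances(graph)
    emb = classical_mds(G, d)
    return Embedding(
        coords=emb.coords, eigenvalues=emb.eigenvalues, method="isomap", d=d, k_used=k
    )


def pca_embed(X: FeatureMatrix | np.ndarray, d: int) -> Embedding:
    """PCA of the column-centered (not standardized) feature matrix.

    Eigendecomposes the covariance matrix; scores are the centered data
    projected on the top-d eigenvectors, with the same sign convention as
    classical_mds.
    """
    M = _as_matrix(X)
    n, p = M.shape
    if d > p:
        raise ValueError(f"d={d} exceeds the {p} feature columns")
    centered = M - M.mean(axis=0, keepdims=True)
    cov = np.cov(centered, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    V = eigvecs[:, :d]
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    V = V * signs
    coords = centered @ V
    return Embedding(coords=coords, eigenvalues=eigvals, method="pca", d=d)


def elbow_dimension(
    eigenvalues: np.ndarray,
    max_search: int = 10,
    curvature_floor: float = 0.05,
    default: int = 3,
) -> ElbowResult:
    """Automated elbow rule on a descending eigenvalue spectrum.

    The spectrum (positive part, max-normalized) is examined on a log scale;
    the elbow is the dimension just before the point of maximum upward
    curvature (discrete second difference of log10 eigenvalues), i.e. the
    last dimension before the spectrum levels off. The search covers
    positions 2..min(max_search, len-1). A strictly geometric decay has zero
    curvature everywhere; when the maximum curvature falls below
    `curvature_floor` the elbow is flagged as unclear and `default` is
    returned.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("elbow rule needs at least three eigenvalues")
    lam = lam[lam > 0]
    if lam.size < 3:
        raise ValueError("elbow rule needs at least three positive eigenvalues")
    s = np.log10(lam / lam[0])
    hi = min(max_search, lam.size - 1)  # 1-based interior positions 2..hi
    j = np.arange(2, hi + 1)
    curv = s[j - 2] - 2.0 * s[j - 1] + s[j]
    best = int(np.argmax(curv))
    if curv[best] < curvature_floor:
        return ElbowResult(dimension=default, curvature=float(curv[best]), clear=False)
    return ElbowResult(
        dimension=int(j[best]) - 1, curvature=float(curv[best]), clear=True
    )


def trustworthiness(
    X: FeatureMatrix | np.ndarray, Y: Embedding | np.ndarray, n_neighbors: int = 5
) -> float:
    """Neighborhood-preservation score of an embedding, in [0, 1].

    T = 1 - 2 / (n K (2n - 3K - 1)) * sum_i sum_{j in U_K(i)} (rank_X(i,j) - K)

    where U_K(i) are the points inside the embedding's K-neighborhood of i
    that are not inside the original-space K-neighborhood, and rank_X(i, j)
    is j's closeness rank to i in the original space (nearest = 1).
    """
    Xm = _as_matrix(X)
    Ym = Y.coords if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    n = Xm.shape[0]
    K = int(n_neighbors)
    if not 1 <= K < n / 2:
        raise ValueError(f"n_neighbors must lie in [1, n/2), got {K} for n={n}")
    DX = pairwise_euclidean(Xm)
    DY = pairwise_euclidean(Ym)
    np.fill_diagonal(DX, np.inf)
    np.fill_diagonal(DY, np.inf)
    penalty = 0.0
    for i in range(n):
        ranks_x = rankdata(DX[i], method="ordinal")  # nearest = 1, self last
        nn_x = set(np.argsort(DX[i], kind="stable")[:K])
        nn_y = np.argsort(DY[i], kind="stable")[:K]
        for j in nn_y:
            if j not in nn_x:
                penalty += ranks_x[j] - K
    return float(1.0 - 2.0 * penalty / (n * K * (2 * n - 3 * K - 1)))


def explained_variance(eigenvalues: np.ndarray, d: int) -> float:
    """Cumulative explained variance (%) of the top-d eigenvalues.

    Negative eigenvalues are excluded from the denominator (and cannot be in
    the numerator, since coordinates only use positive ones).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    lam = np.asarray(eigenvalues, dtype=float)
    pos = lam[lam > 0]
    if pos.size == 0:
        raise ValueError("no positive eigenvalues")
    top = np.sort(pos)[::-1][:d]
    return float(100.0 * top.sum() / pos.sum())
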