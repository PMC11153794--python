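"""Radial-unit clustering: PCA reduction, K-means initialization, and Potts
Markov-random-field refinement.

The 60-dimensional laminar signals are column-centred and reduced to the
smallest number of principal components explaining the configured variance
fraction (95% by default); scores are z-normalized per component. K-means
(k-means++ seeding, fixed RNG) provides the initial labelling, which an
iterated-conditional-modes (ICM) sweep over the unit adjacency graph then
regularizes under the energy

    E(c) = sum_i ||x_i - mu_{c_i}||^2 + beta * sum_{(i,j) in E} 1[c_i != c_j]

with centroid re-estimation between sweeps. Labels are updated sequentially
in unit-ID order, so the energy is non-increasing sweep to sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .coords import RadialUnitSet
from .features import SignalMatrix


@dataclass
class ReducedScores:
    """Z-normalized PCA scores retained to the variance target."""

    scores: np.ndarray  # (n_units, m)
    explained_variance_ratio: np.ndarray  # all components
    n_components: int
    mean: np.ndarray  # column means of the input features
    components: np.ndarray  # (m, n_features)


@dataclass
class ParcelLabels:
    labels: np.ndarray  # (n_units,) int in [0, K)
    n_clusters: int
    centroids: Optional[np.ndarray] = None  # (K, m) in score space
    energy: Optional[float] = None
    energy_trace: Optional[np.ndarray] = None  # per-sweep energies (ICM)


@dataclass
class UnitAdjacency:
    """Symmetrized KNN graph over unit centres (no self-loops)."""

    neighbors: List[np.ndarray]  # adjacency lists, sorted

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    def edges(self) -> np.ndarray:
        out = [
            (i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs if j > i
        ]
        return np.array(out, dtype=np.int64).reshape(-1, 2)


def pca_reduce(features: np.ndarray, var_fraction: float = 0.95) -> ReducedScores:
    """Column-centred PCA keeping the smallest m components whose cumulative
    explained variance reaches ``var_fraction``; scores z-normalized."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate feature matrix: zero variance")
    from sklearn.decomposition import PCA

    pca = PCA(svd_solver="full")
    scores_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(ratios), var_fraction - 1e-12) + 1)
    m = min(m, scores_full.shape[1])
    scores = scores_full[:, :m]
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return ReducedScores(
        scores=scores / sd,
        explained_variance_ratio=ratios,
        n_components=m,
        mean=pca.mean_,
        components=pca.components_[:m],
    )


def kmeans_init(
    scores: ReducedScores, n_clusters: int, seed: int, n_init: int = 10
) -> ParcelLabels:
    """K-means (k-means++, fixed seed) on the reduced scores."""
    X = scores.scores
    if n_clusters > X.shape[0]:
        raise ValueError(f"K={n_clusters} exceeds number of units {X.shape[0]}")
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=n_clusters, n_init=n_init, random_state=int(seed)
    ).fit(X)
    return ParcelLabels(
        labels=km.labels_.astype(np.int64),
        n_clusters=n_clusters,
        centroids=km.cluster_centers_,
    )


def build_adjacency(
    units: RadialUnitSet | np.ndarray, n_neighbors: int = 6
) -> UnitAdjacency:
    """Symmetrized KNN graph over unit centres in physical coordinates.

    Accepts a :class:`RadialUnitSet` or an (n, d) array of centre
    coordinates directly.
    """
    if isinstance(units, RadialUnitSet):
        centers = units.surface.centers_um().astype(np.float64)
    else:
        centers = np.asarray(units, dtype=np.float64)
    n = centers.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    from sklearn.neighbors import NearestNeighbors

    k = min(n_neighbors + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(centers)
    _, idx = nn.kneighbors(centers)
    sets: List[set] = [set() for _ in range(n)]
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            sets[i].add(int(j))
            sets[int(j)].add(i)
    neighbors = [np.array(sorted(s), dtype=np.int64) for s in sets]
    return UnitAdjacency(neighbors=neighbors)


def potts_energy(
    labels: np.ndarray,
    scores: np.ndarray,
    centroids: np.ndarray,
    adj: UnitAdjacency,
    beta: float,
) -> float:
    data = float(((scores - centroids[labels]) ** 2).sum())
    e = adj.edges()
    smooth = float((labels[e[:, 0]] != labels[e[:, 1]]).sum()) if len(e) else 0.0
    return data + beta * smooth


def mrf_refine(
    init: ParcelLabels,
    scores: ReducedScores,
    adj: UnitAdjacency,
    beta: float = 1.0,
    max_sweeps: int = 100,
) -> ParcelLabels:
    """ICM refinement of the Potts-regularized K-means objective.

    Each sweep updates labels sequentially in unit-ID order (greedy argmin
    of data cost plus beta times disagreeing neighbours), then re-estimates
    centroids; both steps lower the energy, so it is non-increasing. Stops
    at a sweep with no label change or at ``max_sweeps`` (returning the best
    state with a warning). Empty clusters are allowed: their centroids stay
    frozen until (if ever) reoccupied.
    """
    X = scores.scores
    n, _ = X.shape
    K = init.n_clusters
    labels = init.labels.astype(np.int64).copy()
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("init labels out of range")
    centroids = np.zeros((K, X.shape[1]))
    for k in range(K):
        m = labels == k
        centroids[k] = X[m].mean(axis=0) if m.any() else (
            init.centroids[k] if init.centroids is not None else X.mean(axis=0)
        )

    energy = potts_energy(labels, X, centroids, adj, beta)
    energies = [energy]
    converged = False
    for _ in range(max_sweeps):
        changed = 0
        # data costs against the current centroids
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        for i in range(n):
            nbr_labels = labels[adj.neighbors[i]]
            agree = np.bincount(nbr_labels, minlength=K)
            cost = d2[i] + beta * (len(nbr_labels) - agree)
            new = int(np.argmin(cost))
            if new != labels[i]:
                labels[i] = new
                changed += 1
        for k in range(K):
            m = labels == k
            if m.any():
                centroids[k] = X[m].mean(axis=0)
        energy = potts_energy(labels, X, centroids, adj, beta)
        if energies and energy > energies[-1] + 1e-9:
            raise AssertionError("ICM energy increased — internal error")
        energies.append(energy)
        if changed == 0:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("ICM hit max_sweeps without converging", stacklevel=2)
    return ParcelLabels(
        labels=labels, n_clusters=K, centroids=centroids, energy=energy,
        energy_trace=np.array(energies),
    )


def cluster_profiles(
    labels: ParcelLabels, signals: List[SignalMatrix]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster mean and SD laminar curves.

    Returns ``(cluster_ids, means, sds)`` with means/sds shaped
    (n_present_clusters, n_laminates, n_grades); empty clusters are omitted
    with a warning.
    """
    lab = labels.labels
    stacked = np.stack([s.values for s in signals])
    present = []
    means = []
    sds = []
    for k in range(labels.n_clusters):
        m = lab == k
        if not m.any():
            import warnings

            warnings.warn(f"cluster {k} is empty; omitted", stacklevel=2)
            continue
        present.append(k)
        means.append(stacked[m].mean(axis=0))
        sds.append(stacked[m].std(axis=0, ddof=0))
    return np.array(present), np.stack(means), np.stack(sds)
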