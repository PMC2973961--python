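"""The clustering ensemble behind the agreement matrix.

Twelve default members: four dissimilarity-based methods (complete-linkage
hierarchical, divisive DIANA, a fuzzy 'fanny' stand-in, PAM k-medoids) run
with Pearson-correlation and Manhattan metrics, plus four feature-space
methods with the Euclidean metric (k-means, fuzzy c-means, a 1-D
self-organizing map, and a Gaussian mixture).  Each member produces one hard
partition; fuzzy members are hardened by maximal membership (ties -> lowest
cluster index).  PAM, DIANA, fuzzy c-means and the SOM are implemented here
because no maintained Python port ships them; the 'fanny' slot is fuzzy
c-means on the metric's feature space (z-scored rows for Pearson), recorded
as a substitution.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DEFAULT_MEMBERS",
    "ClusteringEnsemble",
    "run_ensemble",
    "pam",
    "diana",
    "fuzzy_cmeans",
    "som_1d",
]

DEFAULT_MEMBERS: tuple[tuple[str, str], ...] = (
    ("hclust", "pearson"),
    ("hclust", "manhattan"),
    ("diana", "pearson"),
    ("diana", "manhattan"),
    ("fanny", "pearson"),
    ("fanny", "manhattan"),
    ("pam", "pearson"),
    ("pam", "manhattan"),
    ("kmeans", "euclidean"),
    ("cmeans", "euclidean"),
    ("som", "euclidean"),
    ("mclust", "euclidean"),
)

_DISSIMILARITY_METHODS = {"hclust", "diana", "pam"}


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows get distance 1."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    R[norms == 0, :] = 0.0
    R[:, norms == 0] = 0.0
    np.fill_diagonal(R, 1.0)
    D = 1.0 - np.clip(R, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def _dissimilarity(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pearson":
        return _pearson_distance(X)
    if metric == "manhattan":
        return squareform(pdist(X, metric="cityblock"))
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    raise ValueError(f"unknown metric {metric!r}")


def _feature_space(X: np.ndarray, metric: str) -> np.ndarray:
    # Pearson metric: z-score rows so Euclidean geometry mirrors correlation
    if metric == "pearson":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        return (X - mu) / np.where(sd == 0, 1.0, sd)
    return X


def _pam_build(D: np.ndarray, n_clusters: int) -> np.ndarray:
    """Kaufman-Rousseeuw BUILD: greedy deterministic medoid initialisation."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < n_clusters:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, D[:, new])
    return np.asarray(medoids)


def pam(D: np.ndarray, n_clusters: int, rng: np.random.Generator, n_init: int = 4) -> np.ndarray:
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    BUILD initialisation plus Voronoi-style alternation (assign to nearest
    medoid, re-centre each medoid within its cluster); a few random restarts
    guard against local optima, and the lowest total cost wins.
    """
    n = D.shape[0]
    best_labels, best_cost = None, np.inf
    inits = [_pam_build(D, n_clusters)] + [
        rng.choice(n, size=n_clusters, replace=False) for _ in range(n_init)
    ]
    for medoids in inits:
        for _it in range(100):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(n_clusters):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def diana(D: np.ndarray, n_clusters: int) -> np.ndarray:
    """Classic divisive analysis clustering on a dissimilarity matrix.

    Repeatedly splits the cluster with the largest diameter: the object
    with the highest average dissimilarity seeds a splinter group, and
    objects defect while their affinity for the splinter group exceeds
    their affinity for the remainder.
    """
    n = D.shape[0]
    clusters: list[np.ndarray] = [np.arange(n)]
    while len(clusters) < n_clusters:
        diameters = [D[np.ix_(c, c)].max() if c.size > 1 else 0.0 for c in clusters]
        target = int(np.argmax(diameters))
        if diameters[target] == 0.0:
            break  # all remaining clusters are singletons/duplicates
        cluster = clusters.pop(target)
        sub = D[np.ix_(cluster, cluster)]
        avg = sub.sum(axis=1) / (cluster.size - 1)
        splinter = [int(np.argmax(avg))]
        rest = [i for i in range(cluster.size) if i not in splinter]
        while len(rest) > 1:
            r = np.array(rest)
            d_spl = sub[np.ix_(r, splinter)].mean(axis=1)
            d_rest = sub[np.ix_(r, r)].sum(axis=1) / (len(rest) - 1)  # diag is 0
            gains = d_rest - d_spl
            k = int(np.argmax(gains))
            if gains[k] <= 0:
                break
            splinter.append(rest.pop(k))
        clusters.append(cluster[splinter])
        clusters.append(cluster[rest])
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


def fuzzy_cmeans(
    X: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator,
    m: float = 1.2,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> np.ndarray:
    """Fuzzy c-means (Euclidean), hardened by maximal membership.

    The fuzzifier defaults to 1.2, not the textbook 2.0: for
    high-dimensional expression profiles large fuzzifiers drive every
    membership towards 1/k (fuzzy collapse) and the hardened partition
    degenerates; values around 1.1-1.5 are the standard recommendation for
    microarray profiles.
    """
    n = X.shape[0]
    U = rng.random((n, n_clusters))
    U /= U.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(U_new - U)) < tol:
            U = U_new
            break
        U = U_new
    return np.argmax(U, axis=1)  # argmax takes the lowest index on ties


def som_1d(
    X: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator,
    n_epochs: int = 30,
) -> np.ndarray:
    """Batch self-organizing map on a 1 x n_clusters grid.

    The codebook is seeded by farthest-point (maxmin) selection of data
    rows, ordered along the first principal component to respect the grid
    topology; the Gaussian neighbourhood then anneals from width 1.0 down
    to 0.1.  Starting narrow keeps well-separated seed patterns from being
    smeared together (the dead-unit failure of wide-neighbourhood starts);
    objects are assigned to their best-matching unit, so the partition may
    have fewer than n_clusters occupied units.
    """
    n, d = X.shape
    start = int(np.argmin(((X - X.mean(axis=0)) ** 2).sum(axis=1)))
    seeds = [start]
    dmin = ((X - X[start]) ** 2).sum(axis=1)
    while len(seeds) < n_clusters:
        nxt = int(np.argmax(dmin))
        seeds.append(nxt)
        dmin = np.minimum(dmin, ((X - X[nxt]) ** 2).sum(axis=1))
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    order = np.argsort(Xc[seeds] @ Vt[0])
    codebook = X[np.asarray(seeds)[order]].astype(float).copy()
    grid = np.arange(n_clusters, dtype=float)
    sigmas = np.geomspace(1.0, 0.1, n_epochs)
    for sigma in sigmas:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2) / (2 * sigma**2))  # (k, n)
        denom = h.sum(axis=1)
        nonzero = denom > 1e-12
        codebook[nonzero] = (h[nonzero] @ X) / denom[nonzero, None]
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _run_member(
    method: str, metric: str, X: np.ndarray, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    if method in _DISSIMILARITY_METHODS:
        D = _dissimilarity(X, metric)
        if method == "hclust":
            Z = linkage(squareform(D, checks=False), method="complete")
            return fcluster(Z, t=n_clusters, criterion="maxclust") - 1
        if method == "diana":
            return diana(D, n_clusters)
        return pam(D, n_clusters, rng)
    F = _feature_space(X, metric)
    if method == "fanny":  # substituted by fuzzy c-means on the metric's feature space
        return fuzzy_cmeans(F, n_clusters, rng)
    if method == "cmeans":
        return fuzzy_cmeans(F, n_clusters, rng)
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=5, random_state=int(rng.integers(2**31)))
        return km.fit_predict(F)
    if method == "som":
        return som_1d(F, n_clusters, rng)
    if method == "mclust":
        gm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="diag",
            reg_covar=1e-4,
            n_init=2,
            random_state=int(rng.integers(2**31)),
        )
        return gm.fit_predict(F)
    raise ValueError(f"unknown ensemble method {method!r}")


class ClusteringEnsemble(BaseEstimator):
    """Run a diverse set of clustering algorithms and collect their partitions.

    Parameters
    ----------
    n_clusters : int
        Input number of clusters handed to every member (>= 2).
    members : sequence of (method, metric) pairs, optional
        Defaults to the 12-member ensemble in :data:`DEFAULT_MEMBERS`.
    random_state : int, optional
        Master seed; each member receives an independently derived stream.

    Attributes
    ----------
    labels_matrix_ : ndarray of shape (n_members_run, n_objects)
        One hard partition per member that converged.
    members_run_ : list of (method, metric)
        Members that produced a partition (failed members are dropped with
        a warning).
    """

    def __init__(self, n_clusters: int = 7, members=None, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.members = members
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D objects x features matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters objects")
        members = tuple(self.members) if self.members is not None else DEFAULT_MEMBERS
        if not members:
            raise ValueError("members must be non-empty")

        seed_seq = np.random.SeedSequence(self.random_state)
        child_seqs = seed_seq.spawn(len(members))
        labels_rows = []
        ran = []
        for (method, metric), child in zip(members, child_seqs):
            rng = np.random.default_rng(child)
            try:
                labels = np.asarray(_run_member(method, metric, X, self.n_clusters, rng))
            except Exception as exc:  # noqa: BLE001 - member failure is survivable
                warnings.warn(
                    f"ensemble member ({method}, {metric}) failed and is excluded: {exc}",
                    stacklevel=2,
                )
                continue
            labels_rows.append(labels)
            ran.append((method, metric))
        if not labels_rows:
            raise RuntimeError("every ensemble member failed")
        self.labels_matrix_ = np.vstack(labels_rows)
        self.members_run_ = ran
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict_matrix(self, X) -> np.ndarray:
        """Fit and return the (n_members, n_objects) label matrix."""
        return self.fit(X).labels_matrix_

    @property
    def n_members_(self) -> int:
        check_is_fitted(self, "labels_matrix_")
        return self.labels_matrix_.shape[0]


def run_ensemble(profiles, n_clusters: int, members=None, random_state=None) -> np.ndarray:
    """Functional wrapper: label matrix (members x objects) for ``profiles``."""
    ens = ClusteringEnsemble(n_clusters=n_clusters, members=members, random_state=random_state)
    return ens.fit_predict_matrix(np.asarray(profiles, dtype=float))
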