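"""Module discovery from an averaged agreement matrix.

The discovery loop alternates two steps at a confidence level delta:

1. *Clusterable-subset selection* — genes carrying moderate agreement
   entries (strictly between 1-delta and delta) are greedily removed, worst
   offender first, until every remaining pair is either confidently
   coexpressed (>= delta) or confidently not (<= 1-delta).
2. *Agreement clustering* — agglomeration from singletons where two
   clusters merge only if every cross pair agrees at >= delta
   (complete linkage on the agreement matrix).

The removed genes form the next iteration's domain; iteration stops once a
round produces no multi-gene cluster.  Clusters are then filtered by a
resampling-based size threshold, and similar expression patterns can
optionally be merged under a homogeneity-plus-separation objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .agreement import AgreementMatrix, probeset_agreement
from .ensemble import ClusteringEnsemble

__all__ = [
    "ModuleSet",
    "SignificanceDistribution",
    "select_clusterable",
    "agreement_cluster",
    "iterate_discovery",
    "AgreementClustering",
    "resample_profiles",
    "random_cluster_sizes",
    "significance_threshold",
    "filter_significant",
    "pattern_similarity",
    "objective",
    "merge_similar",
]


# ---------------------------------------------------------------------------
# module container


@dataclass
class ModuleSet:
    """Disjoint gene clusters with provenance and significance."""

    clusters: list[list[str]]
    provenance: list[int] = field(default_factory=list)  # discovery iteration per cluster
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & set(c):
                raise ValueError("clusters must be pairwise disjoint")
            seen |= set(c)
        if not self.provenance:
            self.provenance = [1] * len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        """Cluster significance: in this framework simply the cluster size."""
        return [len(c) for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def assigned(self) -> list[str]:
        return [g for c in self.clusters for g in c]

    def labels(self) -> dict[str, int]:
        """gene -> 0-based module id (unassigned genes omitted)."""
        return {g: p for p, c in enumerate(self.clusters) for g in c}


# ---------------------------------------------------------------------------
# selection and clustering


def _moderate_mask(entries: np.ndarray, delta: float) -> np.ndarray:
    mask = (entries > 1.0 - delta) & (entries < delta)
    np.fill_diagonal(mask, False)
    return mask


def select_clusterable(am: AgreementMatrix, delta: float = 0.7):
    """Greedy removal of genes with moderate agreement entries.

    Repeatedly removes the gene carrying the highest number of entries
    strictly inside (1-delta, delta) (ties -> lowest index), recounting
    after each removal, until no moderate entry remains.  Returns
    ``(selected_ids, removed_ids)`` with ``removed_ids`` in removal order.
    """
    if not 0.5 < delta <= 1.0:
        raise ValueError("delta must lie in (0.5, 1]")
    entries = am.entries
    active = list(range(len(am.object_ids)))
    removed: list[int] = []
    while active:
        sub = entries[np.ix_(active, active)]
        counts = _moderate_mask(sub, delta).sum(axis=1)
        worst = int(np.argmax(counts))  # argmax -> lowest index on ties
        if counts[worst] == 0:
            break
        removed.append(active.pop(worst))
    ids = am.object_ids
    return [ids[i] for i in active], [ids[i] for i in removed]


def agreement_cluster(am: AgreementMatrix, delta: float = 0.7) -> list[list[str]]:
    """Agglomerate a clusterable subset under a complete-linkage constraint.

    Starts from singletons and merges two clusters only when *every* cross
    pair has agreement >= delta; among admissible merges, the pair with the
    highest mean cross-agreement is taken (ties -> first in index order).
    Stops when no admissible merge remains.
    """
    n = len(am.object_ids)
    entries = am.entries
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best, best_mean = None, -1.0
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = entries[np.ix_(clusters[a], clusters[b])]
                if cross.min() >= delta and cross.mean() > best_mean + 1e-15:
                    best, best_mean = (a, b), cross.mean()
        if best is None:
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    ids = am.object_ids
    return [[ids[i] for i in c] for c in clusters]


def iterate_discovery(am: AgreementMatrix, delta: float = 0.7) -> ModuleSet:
    """Repeat selection + clustering on the successively removed domain.

    Each round selects a clusterable subset of the current domain, clusters
    it, and hands the removed genes to the next round.  A round that yields
    no cluster of two or more genes (or selects nothing) terminates the
    loop; its genes are reported as unassigned.
    """
    clusters: list[list[str]] = []
    provenance: list[int] = []
    domain = list(am.object_ids)
    iteration = 0
    while domain:
        iteration += 1
        sub = am.subset(domain)
        selected, removed = select_clusterable(sub, delta)
        if not selected:
            break
        found = agreement_cluster(am.subset(selected), delta)
        if not any(len(c) >= 2 for c in found):
            break
        clusters.extend(found)
        provenance.extend([iteration] * len(found))
        if not removed:
            domain = []
            break
        domain = removed
    return ModuleSet(clusters=clusters, provenance=provenance, unassigned=domain)


class AgreementClustering:
    """scikit-learn-style wrapper around the iterative discovery procedure.

    Operates on a precomputed agreement matrix (pass the square matrix, or
    an :class:`AgreementMatrix`, to :meth:`fit`).

    Attributes
    ----------
    labels_ : ndarray of shape (n_objects,)
        0-based module ids; -1 for unassigned objects.
    module_set_ : ModuleSet
    """

    def __init__(self, delta: float = 0.7):
        self.delta = delta

    def get_params(self, deep: bool = True) -> dict:
        return {"delta": self.delta}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        am = X if isinstance(X, AgreementMatrix) else AgreementMatrix(
            object_ids=[f"obj{i}" for i in range(np.asarray(X).shape[0])],
            entries=np.asarray(X, dtype=float),
        )
        self.module_set_ = iterate_discovery(am, self.delta)
        lab = self.module_set_.labels()
        self.labels_ = np.array([lab.get(o, -1) for o in am.object_ids])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# cluster significance by resampling


@dataclass
class SignificanceDistribution:
    """Empirical cluster-size distribution under resampled (null) data."""

    random_cluster_sizes: list[int]

    def p_value(self, cs: int) -> float:
        """Fraction of random clusters at least as large as ``cs``."""
        sizes = self.random_cluster_sizes
        if not sizes:
            return 0.0
        return sum(s >= cs for s in sizes) / len(sizes)

    def threshold(self, p: float = 0.05) -> int:
        """Smallest cluster size whose null p-value is <= p."""
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        if not self.random_cluster_sizes:
            warnings.warn("no random clusters found; defaulting threshold to 2", stacklevel=2)
            return 2
        for cs in range(2, max(self.random_cluster_sizes) + 2):
            if self.p_value(cs) <= p:
                return cs
        raise AssertionError("unreachable: p-value is 0 above the maximum size")


def resample_profiles(
    profiles: np.ndarray, rng: np.random.Generator, scheme: str = "permutation-hull"
):
    """One null resample of an objects x timepoints profile matrix.

    ``permutation`` independently permutes each row's entries, destroying
    shared temporal structure while preserving each profile's value
    distribution.  ``convex-hull`` draws each null profile as a random
    convex combination of observed rows, preserving the data's envelope but
    erasing gene identity.  ``permutation-hull`` (default) composes the
    two — convex combinations of independently permuted rows — so the null
    keeps the data's overall spread and smoothness while carrying no real
    coexpression structure; this is the calibration null used for cluster
    significance.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]

    def permute(X):
        out = X.copy()
        for row in out:
            rng.shuffle(row)
        return out

    def hull(X):
        w = rng.dirichlet(np.ones(min(n, 4)), size=n)
        idx = np.array([rng.choice(n, size=w.shape[1], replace=False) for _ in range(n)])
        return np.einsum("ij,ijk->ik", w, X[idx])

    if scheme == "permutation":
        return permute(profiles)
    if scheme == "convex-hull":
        return hull(profiles)
    if scheme == "permutation-hull":
        return hull(permute(profiles))
    raise ValueError(f"unknown resampling scheme {scheme!r}")


def random_cluster_sizes(
    profiles,
    n_clusters: int,
    delta: float = 0.7,
    n_resamples: int = 20,
    scheme: str = "permutation-hull",
    members=None,
    random_state=None,
) -> SignificanceDistribution:
    """Cluster-size null distribution from resampled single-condition data.

    Each resample rebuilds the ensemble agreement matrix (probesets treated
    as genes, K = 1) at the given input cluster number and runs the full
    iterative discovery; the sizes of all resulting multi-gene clusters are
    pooled.  Singleton "clusters" are not counted: the significance step
    exists to remove trivial clusters, and letting the null's own trivia
    inflate the denominator would bias every p-value towards significance.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    profiles = np.asarray(profiles, dtype=float)
    seed_seq = np.random.SeedSequence(random_state)
    sizes: list[int] = []
    for child in seed_seq.spawn(n_resamples):
        rng = np.random.default_rng(child)
        null = resample_profiles(profiles, rng, scheme)
        ens = ClusteringEnsemble(
            n_clusters=n_clusters, members=members, random_state=int(rng.integers(2**31))
        )
        am = probeset_agreement(ens.fit_predict_matrix(null))
        ms = iterate_discovery(am, delta)
        sizes.extend(s for s in ms.sizes if s >= 2)
    return SignificanceDistribution(random_cluster_sizes=sizes)


def significance_threshold(
    profiles,
    n_clusters: int,
    delta: float = 0.7,
    n_resamples: int = 20,
    p: float = 0.05,
    scheme: str = "permutation-hull",
    members=None,
    random_state=None,
) -> int:
    """Size cutoff at p-value ``p`` from the resampled null distribution."""
    dist = random_cluster_sizes(
        profiles,
        n_clusters,
        delta=delta,
        n_resamples=n_resamples,
        scheme=scheme,
        members=members,
        random_state=random_state,
    )
    return dist.threshold(p)


def filter_significant(ms: ModuleSet, cutoff: int) -> ModuleSet:
    """Keep clusters whose significance (size) is >= cutoff.

    The boundary is inclusive: a cluster exactly at the threshold is kept.
    Genes of dropped clusters join the unassigned pool.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    keep = [i for i, s in enumerate(ms.sizes) if s >= cutoff]
    dropped = [g for i, c in enumerate(ms.clusters) if i not in set(keep) for g in c]
    return ModuleSet(
        clusters=[ms.clusters[i] for i in keep],
        provenance=[ms.provenance[i] for i in keep] if ms.provenance else [],
        unassigned=list(ms.unassigned) + dropped,
    )


# ---------------------------------------------------------------------------
# merging similar patterns


def pattern_similarity(
    profiles_per_condition: list, gene_map_per_condition: list[dict[str, list[str]]], genes: list[str]
) -> np.ndarray:
    """Per-condition gene-level Pearson similarity matrices.

    For each condition, computes the probeset-profile correlation matrix and
    averages it over the probeset pairs of each gene pair (zero-variance
    profiles correlate at 0, with a warning).  Returns an array of shape
    (K, n_genes, n_genes).
    """
    out = []
    for profiles, gmap in zip(profiles_per_condition, gene_map_per_condition):
        ids = [str(i) for i in profiles.index] if hasattr(profiles, "index") else None
        X = np.asarray(profiles, dtype=float)
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        if np.any(norms == 0):
            warnings.warn("zero-variance profile; its correlations are treated as 0", stacklevel=2)
        safe = np.where(norms == 0, 1.0, norms)
        R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
        R[norms == 0, :] = 0.0
        R[:, norms == 0] = 0.0
        pos = {p: i for i, p in enumerate(ids)} if ids else None
        n = len(genes)
        S = np.empty((n, n))
        groups = []
        for g in genes:
            ps = gmap[g]
            groups.append([pos[p] for p in ps] if pos else list(ps))
        for i in range(n):
            Ri = R[groups[i]]
            for j in range(i, n):
                S[i, j] = S[j, i] = Ri[:, groups[j]].mean()
        out.append(S)
    return np.asarray(out)


def _objective_from_sim(sim: np.ndarray, clusters: list[list[int]]) -> float:
    """Homogeneity + separation of a clustering, given (K, n, n) gene similarities."""
    K = sim.shape[0]
    n = len(clusters)
    hom = 0.0
    for members in clusters:
        size = len(members)
        if size < 2:
            continue  # singleton clusters contribute no homogeneity term
        for k in range(K):
            block = sim[k][np.ix_(members, members)]
            hom += (block.sum() - np.trace(block)) / (size * (size - 1))
    hom /= K * n
    sep = 0.0
    if n >= 2:
        for p in range(n):
            for q in range(p + 1, n):
                for k in range(K):
                    cross = sim[k][np.ix_(clusters[p], clusters[q])]
                    sep += (1.0 - cross).mean()
        sep *= 2.0 / (K * n * (n - 1))
    return hom + sep


def objective(
    ms: ModuleSet, profiles_per_condition, gene_map_per_condition, _sim=None
) -> float:
    """Sum of average within-cluster homogeneity and between-cluster separation.

    Similarity between two genes in a condition is the mean Pearson r over
    their probeset-profile pairs; dissimilarity is the Pearson distance
    1 - r.  Homogeneity averages similarity over ordered within-cluster
    gene pairs (singletons skipped); separation averages dissimilarity over
    cluster pairs; both are averaged over conditions and clusters.
    """
    genes = ms.assigned
    index = {g: i for i, g in enumerate(genes)}
    sim = _sim if _sim is not None else pattern_similarity(
        profiles_per_condition, gene_map_per_condition, genes
    )
    clusters = [[index[g] for g in c] for c in ms.clusters]
    return _objective_from_sim(sim, clusters)


def merge_similar(ms: ModuleSet, profiles_per_condition, gene_map_per_condition) -> ModuleSet:
    """Greedy merging of similar expression patterns.

    At each step, evaluates the homogeneity+separation objective after every
    candidate pairwise merge and performs the merge with the largest strict
    increase; stops when every candidate merge would not increase the
    objective.  The objective is non-decreasing over accepted merges and
    the cluster count never grows.
    """
    if ms.n_clusters < 2:
        return ms
    genes = ms.assigned
    index = {g: i for i, g in enumerate(genes)}
    sim = pattern_similarity(profiles_per_condition, gene_map_per_condition, genes)
    clusters = [[index[g] for g in c] for c in ms.clusters]
    prov = list(ms.provenance)
    current = _objective_from_sim(sim, clusters)
    while len(clusters) >= 2:
        best, best_val = None, current
        for p in range(len(clusters)):
            for q in range(p + 1, len(clusters)):
                trial = [c for i, c in enumerate(clusters) if i not in (p, q)]
                trial.append(clusters[p] + clusters[q])
                val = _objective_from_sim(sim, trial)
                if val > best_val + 1e-12:
                    best, best_val = (p, q), val
        if best is None:
            break
        p, q = best
        merged = clusters[p] + clusters[q]
        prov_merged = min(prov[p], prov[q])
        clusters = [c for i, c in enumerate(clusters) if i not in (p, q)] + [merged]
        prov = [v for i, v in enumerate(prov) if i not in (p, q)] + [prov_merged]
        current = best_val
    return ModuleSet(
        clusters=[[genes[i] for i in c] for c in clusters],
        provenance=prov,
        unassigned=list(ms.unassigned),
    )
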