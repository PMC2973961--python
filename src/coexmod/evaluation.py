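"""Scoring recovered modules against known class structure, plus the
per-condition intersection baseline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .discovery import ModuleSet, filter_significant, iterate_discovery
from .agreement import probeset_agreement
from .ensemble import ClusteringEnsemble, pam, _dissimilarity
from sklearn.mixture import GaussianMixture

__all__ = [
    "EvaluationReport",
    "adjusted_rand_index",
    "evaluate_recovery",
    "intersection_baseline",
    "single_condition_partition",
]


@dataclass
class EvaluationReport:
    n_selected: int
    n_clusters: int
    ari: float | None  # None when nothing was selected

    @property
    def accuracy_percent(self) -> float | None:
        return None if self.ari is None else 100.0 * self.ari


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Permutation-model adjusted Rand index between two labelings.

    Accepts dicts (object -> label) over the same object set, or two
    equal-length label sequences.
    """
    if isinstance(partition_a, dict) or isinstance(partition_b, dict):
        if not (isinstance(partition_a, dict) and isinstance(partition_b, dict)):
            raise ValueError("both partitions must be dicts, or both sequences")
        if set(partition_a) != set(partition_b):
            raise ValueError("partitions cover different object sets")
        keys = sorted(partition_a)
        a = [partition_a[k] for k in keys]
        b = [partition_b[k] for k in keys]
    else:
        a, b = list(partition_a), list(partition_b)
        if len(a) != len(b):
            raise ValueError("partitions cover different numbers of objects")
    return float(adjusted_rand_score(a, b))


def evaluate_recovery(ms: ModuleSet, labels: dict[str, int]) -> EvaluationReport:
    """Score a ModuleSet against ground-truth labels on the selected domain.

    The adjusted Rand index is computed only over genes assigned to modules;
    counts of selected genes and clusters accompany it.
    """
    assigned = ms.assigned
    missing = [g for g in assigned if g not in labels]
    if missing:
        raise ValueError(f"labels missing for genes: {missing[:5]}")
    if not assigned:
        return EvaluationReport(n_selected=0, n_clusters=0, ari=None)
    found = ms.labels()
    truth = {g: labels[g] for g in assigned}
    ari = adjusted_rand_index({g: found[g] for g in assigned}, truth)
    return EvaluationReport(n_selected=len(assigned), n_clusters=ms.n_clusters, ari=ari)


def intersection_baseline(partitions: list[list[set]], min_size: int = 5) -> ModuleSet:
    """Condition-by-condition intersection of per-condition clusters.

    Starting from the first condition's clusters, repeatedly intersects
    with the next condition's clusters (keeping non-empty pieces), then
    keeps only pieces with strictly more than ``min_size`` genes.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    current = [set(c) for c in partitions[0] if c]
    for part in partitions[1:]:
        nxt = []
        for c in current:
            for d in part:
                piece = c & set(d)
                if piece:
                    nxt.append(piece)
        current = nxt
    kept = [sorted(c) for c in current if len(c) > min_size]
    dropped = sorted(set().union(*[set(c) for c in current]) - set(g for c in kept for g in c)) if current else []
    return ModuleSet(clusters=kept, unassigned=dropped)


def single_condition_partition(
    profiles,
    n_clusters: int,
    method: str = "pam",
    delta: float = 0.7,
    random_state=None,
) -> list[set]:
    """One condition's clusters for the intersection baseline.

    ``method`` is one of ``pam`` (k-medoids, Euclidean), ``gmm`` (Gaussian
    mixture, the model-based stand-in) or ``consensus`` (the
    single-condition agreement-matrix procedure).
    """
    import pandas as pd

    if hasattr(profiles, "index"):
        ids = [str(i) for i in profiles.index]
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        ids = [f"p{i}" for i in range(X.shape[0])]
    rng = np.random.default_rng(random_state)
    if method == "pam":
        labels = pam(_dissimilarity(X, "euclidean"), n_clusters, rng)
    elif method == "gmm":
        gm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="diag",
            reg_covar=1e-4,
            n_init=2,
            random_state=int(rng.integers(2**31)),
        )
        labels = gm.fit_predict(X)
    elif method == "consensus":
        ens = ClusteringEnsemble(n_clusters=n_clusters, random_state=int(rng.integers(2**31)))
        am = probeset_agreement(ens.fit_predict_matrix(X), object_ids=ids)
        ms = iterate_discovery(am, delta)
        return [set(c) for c in ms.clusters]
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    out: dict[int, set] = {}
    for g, lab in zip(ids, labels):
        out.setdefault(int(lab), set()).add(g)
    return list(out.values())
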