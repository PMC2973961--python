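"""Agreement matrices: consensus of many clustering runs as a confidence of
coexpression.

The probeset-level agreement between two objects is the fraction of ensemble
runs assigning them to the same cluster.  Gene-level agreement averages the
probeset-level entries over all probeset pairs of two genes, and the
cross-condition matrix averages the per-condition gene-level matrices —
a unitless statistic that lets heterogeneous platforms be combined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ClusteringEnsemble

__all__ = [
    "AgreementMatrix",
    "probeset_agreement",
    "gene_agreement",
    "average_conditions",
    "moderate_fraction",
    "suggest_nc",
]


@dataclass
class AgreementMatrix:
    """Symmetric matrix of agreement levels in [0, 1] over named objects."""

    object_ids: list[str]
    entries: np.ndarray
    level: str = "probeset-condition"  # or "gene-condition", "gene-averaged"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.object_ids)
        if self.entries.shape != (n, n):
            raise ValueError("entries must be square and match object_ids")
        if not np.allclose(self.entries, self.entries.T, atol=1e-12):
            raise ValueError("agreement matrix must be symmetric")
        if not np.allclose(np.diag(self.entries), 1.0, atol=1e-12):
            raise ValueError("agreement matrix diagonal must be 1")
        if self.entries.min() < -1e-12 or self.entries.max() > 1 + 1e-12:
            raise ValueError("agreement levels must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.object_ids, columns=self.object_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: str = "probeset-condition"):
        return cls(object_ids=[str(i) for i in frame.index], entries=frame.to_numpy(), level=level)

    def subset(self, ids) -> "AgreementMatrix":
        pos = {o: i for i, o in enumerate(self.object_ids)}
        rows = [pos[i] for i in ids]
        return AgreementMatrix(
            object_ids=list(ids), entries=self.entries[np.ix_(rows, rows)], level=self.level
        )


def probeset_agreement(labels, object_ids=None) -> AgreementMatrix:
    """Co-association matrix of a (runs x objects) label matrix.

    Entry (x, y) is the fraction of runs in which x and y share a cluster.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D runs x objects matrix")
    m, n = labels.shape
    if m < 1:
        raise ValueError("need at least one clustering run")
    co = np.zeros((n, n))
    for row in labels:
        co += row[:, None] == row[None, :]
    co /= m
    np.fill_diagonal(co, 1.0)
    if object_ids is None:
        object_ids = [f"obj{i}" for i in range(n)]
    return AgreementMatrix(object_ids=list(object_ids), entries=co)


def gene_agreement(pm: AgreementMatrix, gene_to_probesets: dict[str, list[str]]) -> AgreementMatrix:
    """Average probeset agreement over probeset pairs of each gene pair."""
    pos = {p: i for i, p in enumerate(pm.object_ids)}
    genes = list(gene_to_probesets)
    groups = []
    for g in genes:
        ps = gene_to_probesets[g]
        if not ps:
            raise ValueError(f"gene {g!r} has no probesets")
        try:
            groups.append([pos[p] for p in ps])
        except KeyError as exc:
            raise ValueError(f"gene {g!r} maps to a probeset absent from the matrix: {exc}")
    n = len(genes)
    out = np.empty((n, n))
    for i, gi in enumerate(groups):
        block_i = pm.entries[gi]
        for j in range(i, n):
            out[i, j] = out[j, i] = block_i[:, groups[j]].mean()
    np.fill_diagonal(out, 1.0)
    return AgreementMatrix(object_ids=genes, entries=out, level="gene-condition")


def average_conditions(ams: list[AgreementMatrix]) -> AgreementMatrix:
    """Entrywise mean of per-condition gene-level matrices (same gene set)."""
    if not ams:
        raise ValueError("need at least one agreement matrix")
    ids = ams[0].object_ids
    for am in ams[1:]:
        if am.object_ids != ids:
            raise ValueError("agreement matrices are over different gene sets")
    mean = np.mean([am.entries for am in ams], axis=0)
    np.fill_diagonal(mean, 1.0)
    return AgreementMatrix(object_ids=list(ids), entries=mean, level="gene-averaged")


def moderate_fraction(am: AgreementMatrix, delta: float) -> float:
    """Fraction of off-diagonal entries strictly inside (1 - delta, delta)."""
    n = len(am.object_ids)
    iu = np.triu_indices(n, k=1)
    vals = am.entries[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > 1.0 - delta) & (vals < delta)))


def suggest_nc(
    profiles,
    nc_range=(2, 10),
    delta: float = 0.7,
    members=None,
    random_state=None,
    flatten_eps: float = 0.05,
) -> int:
    """Suggest an input cluster number nc* from the sensitivity of the
    agreement matrix to nc.

    Sweeps nc over ``nc_range`` (inclusive), rebuilding the ensemble
    agreement matrix at each value, and examines two summaries of the
    off-diagonal agreement distribution:

    * the *moderate fraction* f(nc) — entries strictly inside
      (1-delta, delta); and
    * the consensus-distribution area A(nc) = 1 - mean(entries), whose
      relative increase D(nc) = (A(nc+1) - A(nc)) / A(nc) measures how much
      the consensus still changes when one more cluster is allowed.

    When some nc values yield *exactly zero* moderate entries (perfectly
    separable, typically noiseless, data) the finest such resolution is
    returned: the ensemble is unanimous there and any further split
    produces disagreement.  Otherwise nc* is the smallest nc at which the
    consensus distribution has stopped moving (D(nc) < ``flatten_eps``);
    for data with a genuine k-cluster structure A(nc) rises sharply up to k
    and flattens beyond it, while structureless data keeps drifting, in
    which case — every D above the threshold, all resolutions equally
    ambiguous — the smallest nc in the range is returned.
    """
    profiles = np.asarray(profiles, dtype=float)
    lo, hi = int(nc_range[0]), int(nc_range[1])
    hi = min(hi, profiles.shape[0] - 2)
    if lo < 2 or lo > hi:
        raise ValueError(f"empty or invalid nc range ({lo}, {hi})")
    fractions: dict[int, float] = {}
    areas: dict[int, float] = {}
    for nc in range(lo, hi + 2):  # one past hi to evaluate D(hi)
        ens = ClusteringEnsemble(n_clusters=nc, members=members, random_state=random_state)
        am = probeset_agreement(ens.fit_predict_matrix(profiles))
        if nc <= hi:
            fractions[nc] = moderate_fraction(am, delta)
        iu = np.triu_indices(len(am.object_ids), k=1)
        areas[nc] = 1.0 - float(am.entries[iu].mean())
    zero = [nc for nc, f in fractions.items() if f == 0.0]
    if zero:
        return max(zero)
    for nc in range(lo, hi + 1):
        if areas[nc] <= 0:  # unanimous single cluster at this nc
            return nc
        if (areas[nc + 1] - areas[nc]) / areas[nc] < flatten_eps:
            return nc
    return lo
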