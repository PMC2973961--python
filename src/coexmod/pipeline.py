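"""End-to-end cross-condition module discovery as a single estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .agreement import average_conditions, gene_agreement, probeset_agreement, suggest_nc
from .discovery import (
    filter_significant,
    iterate_discovery,
    merge_similar,
    significance_threshold,
)
from .ensemble import ClusteringEnsemble
from .io import ExpressionDataset, GeneMap, condense_replicates

__all__ = ["ConsensusModuleDiscovery"]


class ConsensusModuleDiscovery(BaseEstimator):
    """Discover gene modules coexpressed across multiple conditions.

    Fits on a list of per-condition expression inputs: either
    :class:`~coexmod.io.ExpressionDataset` objects (replicates are condensed
    first) or probeset x timepoint DataFrames.  For every condition a
    clustering ensemble is run at the (suggested or fixed) input cluster
    number, probeset-level agreement matrices are averaged into gene-level
    confidence of coexpression across conditions, and clusters are extracted
    by iterative clusterable-subset selection, filtered by a resampled size
    threshold and optionally merged.

    Parameters
    ----------
    delta : float, default 0.7
        Confidence level of coexpression; pairwise agreements inside
        (1-delta, delta) are treated as ambiguous.
    n_clusters : int or None, default None
        Input cluster number for the ensemble; None sweeps ``nc_range``
        per condition and uses each condition's suggested value.
    nc_range : (int, int), default (2, 10)
        Inclusive sweep range for the suggestion.
    p_value : float, default 0.05
        Cluster-significance level for the resampled size threshold.
    n_resamples : int, default 20
        Null resamples; 0 disables significance filtering.
    resample_scheme : {'permutation-hull', 'permutation', 'convex-hull'}
    merge : bool, default False
        Merge similar expression patterns after significance filtering.
    condense : {'ivw', 'mean'}
        Replicate condensation for ExpressionDataset inputs.
    members : sequence of (method, metric), optional
        Ensemble composition override.
    random_state : int, optional

    Attributes
    ----------
    agreement_ : AgreementMatrix
        Cross-condition (gene-averaged) agreement matrix.
    modules_ : ModuleSet
        Final significant modules.
    labels_ : ndarray
        0-based module id per common gene, -1 when unassigned.
    gene_ids_ : list of str
    nc_used_ : list of int
        Input cluster number per condition.
    size_cutoff_ : int or None
        Significance size threshold actually applied.
    """

    def __init__(
        self,
        delta: float = 0.7,
        n_clusters: int | None = None,
        nc_range: tuple[int, int] = (2, 10),
        p_value: float = 0.05,
        n_resamples: int = 20,
        resample_scheme: str = "permutation-hull",
        merge: bool = False,
        condense: str = "ivw",
        members=None,
        random_state: int | None = None,
    ):
        self.delta = delta
        self.n_clusters = n_clusters
        self.nc_range = nc_range
        self.p_value = p_value
        self.n_resamples = n_resamples
        self.resample_scheme = resample_scheme
        self.merge = merge
        self.condense = condense
        self.members = members
        self.random_state = random_state

    # -- input normalisation -------------------------------------------------

    def _profiles(self, X) -> list[pd.DataFrame]:
        profiles = []
        for item in X:
            if isinstance(item, ExpressionDataset):
                profiles.append(condense_replicates(item, method=self.condense))
            elif isinstance(item, pd.DataFrame):
                profiles.append(item)
            else:
                arr = np.asarray(item, dtype=float)
                profiles.append(
                    pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])])
                )
        return profiles

    @staticmethod
    def _gene_maps(profiles, gene_map) -> tuple[list[dict[str, list[str]]], list[str]]:
        if gene_map is None:
            # every probeset is its own gene; conditions must share ids
            ids = [str(i) for i in profiles[0].index]
            for prof in profiles[1:]:
                if [str(i) for i in prof.index] != ids:
                    raise ValueError(
                        "conditions have different probeset ids; supply a gene_map"
                    )
            return [{g: [g] for g in ids} for _ in profiles], ids
        if isinstance(gene_map, GeneMap):
            maps = list(gene_map.per_condition.values())
            return maps, list(gene_map.common_genes)
        maps = list(gene_map)
        genes = sorted(set(maps[0]).intersection(*[set(m) for m in maps[1:]]))
        return [{g: m[g] for g in genes} for m in maps], genes

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None, gene_map=None):
        profiles = self._profiles(X)
        maps, genes = self._gene_maps(profiles, gene_map)
        if len(genes) == 0:
            raise ValueError("no genes common to all conditions")
        seed_seq = np.random.SeedSequence(self.random_state)
        cond_seeds, sig_seed = seed_seq.spawn(len(profiles)), seed_seq.spawn(1)[0]

        gene_ams = []
        self.nc_used_ = []
        for prof, gmap, child in zip(profiles, maps, cond_seeds):
            keep = sorted({p for ps in gmap.values() for p in ps})
            prof = prof.loc[keep]
            data = prof.to_numpy(dtype=float)
            sub_seeds = child.spawn(2)
            if self.n_clusters is None:
                nc = suggest_nc(
                    data,
                    nc_range=self.nc_range,
                    delta=self.delta,
                    members=self.members,
                    random_state=int(np.random.default_rng(sub_seeds[0]).integers(2**31)),
                )
            else:
                nc = int(self.n_clusters)
            self.nc_used_.append(nc)
            ens = ClusteringEnsemble(
                n_clusters=nc,
                members=self.members,
                random_state=int(np.random.default_rng(sub_seeds[1]).integers(2**31)),
            )
            pm = probeset_agreement(
                ens.fit_predict_matrix(data), object_ids=[str(i) for i in prof.index]
            )
            gene_ams.append(gene_agreement(pm, gmap))

        self.agreement_ = average_conditions(gene_ams)
        modules = iterate_discovery(self.agreement_, self.delta)

        self.size_cutoff_ = None
        if self.n_resamples > 0:
            # null built from the first condition, probesets treated as genes;
            # calibrated at the analysis's typical resolution (median nc) so a
            # single outlier suggestion cannot degenerate the null
            null_nc = int(round(float(np.median(self.nc_used_))))
            first = profiles[0].loc[sorted({p for ps in maps[0].values() for p in ps})]
            self.size_cutoff_ = significance_threshold(
                first.to_numpy(dtype=float),
                n_clusters=null_nc,
                delta=self.delta,
                n_resamples=self.n_resamples,
                p=self.p_value,
                scheme=self.resample_scheme,
                members=self.members,
                random_state=int(np.random.default_rng(sig_seed).integers(2**31)),
            )
            modules = filter_significant(modules, self.size_cutoff_)

        if self.merge and modules.n_clusters >= 2:
            keep_profiles = [
                prof.loc[sorted({p for ps in gmap.values() for p in ps})]
                for prof, gmap in zip(profiles, maps)
            ]
            keyed = [
                pd.DataFrame(p.to_numpy(dtype=float), index=[str(i) for i in p.index])
                for p in keep_profiles
            ]
            modules = merge_similar(modules, keyed, maps)

        self.modules_ = modules
        self.gene_ids_ = list(self.agreement_.object_ids)
        lab = modules.labels()
        self.labels_ = np.array([lab.get(g, -1) for g in self.gene_ids_])
        return self

    def fit_predict(self, X, y=None, gene_map=None):
        return self.fit(X, y=y, gene_map=gene_map).labels_
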