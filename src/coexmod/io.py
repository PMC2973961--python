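"""Expression data ingestion, differential-expression prefiltering and
probeset <-> gene mapping.

A condition's data is a probeset x time x replicate tensor (missing
replicates stored as NaN).  Before the coexpression analysis each dataset is
ANOVA-filtered for probesets that change over time, probesets are mapped to
gene symbols, the gene lists are intersected across conditions, and each
common gene is re-mapped to *all* of its surviving probesets per condition —
multiple probesets of a gene are treated as replicate profiles of that gene
downstream, not averaged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "GeneMap",
    "read_expression_tsv",
    "anova_filter",
    "build_gene_map",
    "condense_replicates",
    "read_geo_soft",
]


@dataclass
class ExpressionDataset:
    """One condition's probeset x time x replicate expression tensor."""

    condition_id: str
    values: np.ndarray  # (n_probesets, n_timepoints, n_replicates), NaN = missing
    timepoints: np.ndarray  # strictly increasing, hours
    probeset_ids: list[str]
    annotation: dict[str, str] | None = None  # probeset -> gene symbol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D probeset x time x replicate tensor")
        if self.values.shape[0] != len(self.probeset_ids):
            raise ValueError("probeset_ids length does not match tensor")
        if self.values.shape[1] != len(self.timepoints):
            raise ValueError("timepoints length does not match tensor")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("duplicate probeset ids")

    @property
    def n_probesets(self) -> int:
        return self.values.shape[0]

    def subset(self, probesets) -> "ExpressionDataset":
        idx = {p: i for i, p in enumerate(self.probeset_ids)}
        rows = [idx[p] for p in probesets]
        ann = None
        if self.annotation is not None:
            ann = {p: self.annotation[p] for p in probesets if p in self.annotation}
        return ExpressionDataset(
            condition_id=self.condition_id,
            values=self.values[rows],
            timepoints=self.timepoints,
            probeset_ids=list(probesets),
            annotation=ann,
        )


@dataclass
class GeneMap:
    """Per-condition gene -> probesets maps restricted to the common gene set."""

    per_condition: dict[str, dict[str, list[str]]]  # condition_id -> gene -> probesets
    common_genes: list[str] = field(default_factory=list)


def read_expression_tsv(path, manifest) -> ExpressionDataset:
    """Read a wide probeset-by-sample TSV using a column manifest.

    ``manifest`` is a path or DataFrame with columns ``column``, ``time_h``,
    ``replicate``; every manifest column must exist in the table and every
    non-index table column must be in the manifest.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probeset ids in {path}: {dups}")
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    required = {"column", "time_h", "replicate"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    missing = set(manifest["column"]) - set(table.columns)
    if missing:
        raise ValueError(f"manifest columns absent from the file: {sorted(missing)}")
    unknown = set(table.columns) - set(manifest["column"])
    if unknown:
        raise ValueError(f"columns not described by the manifest: {sorted(unknown)}")

    for col in manifest["column"]:
        bad = table[col].apply(lambda v: not np.isreal(v) or isinstance(v, str))
        non_numeric = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if non_numeric.any():
            row = table.index[non_numeric.argmax()]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
        del bad

    times = np.sort(manifest["time_h"].unique())
    reps_per_time = manifest.groupby("time_h")["replicate"].nunique()
    n_rep = int(reps_per_time.max())
    values = np.full((table.shape[0], len(times), n_rep), np.nan)
    t_index = {t: j for j, t in enumerate(times)}
    rep_counter: dict[float, int] = {}
    for _, row in manifest.sort_values(["time_h", "replicate"]).iterrows():
        j = t_index[row["time_h"]]
        r = rep_counter.get(row["time_h"], 0)
        rep_counter[row["time_h"]] = r + 1
        values[:, j, r] = pd.to_numeric(table[row["column"]]).to_numpy()
    from pathlib import Path

    return ExpressionDataset(
        condition_id=Path(str(path)).stem,
        values=values,
        timepoints=times,
        probeset_ids=[str(p) for p in table.index],
    )


def anova_filter(ds: ExpressionDataset, alpha: float = 0.05) -> list[str]:
    """Probesets differentially expressed over time: one-way fixed-effects
    ANOVA with time points as groups and replicates as within-group
    observations; keep p < alpha.

    Probesets with fewer than two time groups carrying data, or with no
    within-group variance anywhere (F undefined), are excluded with a
    warning rather than an error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    selected: list[str] = []
    n_skipped = 0
    for i, pid in enumerate(ds.probeset_ids):
        groups = [row[~np.isnan(row)] for row in ds.values[i]]
        groups = [g for g in groups if g.size > 0]
        if len(groups) < 2 or sum(g.size for g in groups) <= len(groups):
            n_skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
        if np.isfinite(p) and p < alpha:
            selected.append(pid)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} probesets excluded from the ANOVA filter "
            "(insufficient groups or replication)",
            stacklevel=2,
        )
    return selected


def build_gene_map(datasets: list[ExpressionDataset], annotations=None) -> GeneMap:
    """Intersect gene symbols across conditions and re-map each common gene
    to all of its (filtered) probesets per condition.

    ``annotations`` may supply per-condition probeset -> gene dicts (same
    order as ``datasets``); otherwise each dataset's own annotation is used.
    Symbols match case-insensitively.
    """
    per_condition: dict[str, dict[str, list[str]]] = {}
    gene_sets: list[set[str]] = []
    display: dict[str, str] = {}
    for idx, ds in enumerate(datasets):
        ann = annotations[idx] if annotations is not None else ds.annotation
        if ann is None:
            raise ValueError(f"no annotation available for {ds.condition_id}")
        g2p: dict[str, list[str]] = {}
        for pid in ds.probeset_ids:
            gene = ann.get(pid)
            if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
                continue
            key = str(gene).upper()
            display.setdefault(key, str(gene))
            g2p.setdefault(key, []).append(pid)
        per_condition[ds.condition_id] = g2p
        gene_sets.append(set(g2p))

    common = set.intersection(*gene_sets) if gene_sets else set()
    if not common:
        warnings.warn("no genes are common to all conditions", stacklevel=2)
    common_sorted = sorted(common)
    restricted = {
        cid: {display[g]: g2p[g] for g in common_sorted} for cid, g2p in per_condition.items()
    }
    return GeneMap(per_condition=restricted, common_genes=[display[g] for g in common_sorted])


def condense_replicates(ds: ExpressionDataset, method: str = "ivw") -> pd.DataFrame:
    """Collapse replicates into one profile of length T per probeset.

    ``method='mean'`` is the plain per-timepoint average.  ``method='ivw'``
    (default) is an inverse-variance-weighted average standing in for a
    full replicate-integration model: each replicate series is weighted by
    the inverse of its residual variance around the per-timepoint mean, so
    a consistently noisy replicate contributes less to the estimated
    profile at every time point.  Variances are floored at the 10th
    percentile of the observed replicate variances so a lucky replicate
    cannot acquire unbounded weight.  With a single replicate, or with
    equal residual variances, both methods coincide.

    Probesets with a time point carrying no data at all are dropped with a
    warning.
    """
    if method not in {"mean", "ivw"}:
        raise ValueError(f"unknown condensation method {method!r}")
    counts = np.sum(~np.isnan(ds.values), axis=2)  # (n_probesets, T)
    keep = np.all(counts >= 1, axis=1)
    if not np.all(keep):
        dropped = [p for p, k in zip(ds.probeset_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} probesets with an empty time point: {dropped[:5]}...",
            stacklevel=2,
        )
    vals = ds.values[keep]
    ids = [p for p, k in zip(ds.probeset_ids, keep) if k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(vals, axis=2)
        if method == "mean" or vals.shape[2] == 1:
            profiles = means
        else:
            resid = vals - means[:, :, None]
            var = np.nanmean(resid**2, axis=1)  # (n_probesets, n_replicates)
            observed = var[np.isfinite(var) & (var > 0)]
            floor = np.percentile(observed, 10) if observed.size else 0.0
            floor = max(floor, np.finfo(float).tiny)
            w = 1.0 / np.maximum(np.where(np.isfinite(var), var, np.inf), floor)
            w3 = np.where(np.isnan(vals), 0.0, w[:, None, :])
            profiles = np.sum(np.nan_to_num(vals) * w3, axis=2) / np.sum(w3, axis=2)
    return pd.DataFrame(profiles, index=pd.Index(ids, name="probeset_id"), columns=ds.timepoints)


def read_geo_soft(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal GEO GDS SOFT (text) reader.

    Returns ``(table, subsets)``: the expression table indexed by ID_REF
    with an IDENTIFIER column and one numeric column per sample, and a
    subset table (subset description / type / sample ids) to let callers
    assign times to samples.  Values are used as deposited.
    """
    subsets = []
    current: dict[str, str] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!dataset_table_begin"):
                in_table = True
                continue
            if line.startswith("!dataset_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
                continue
            if line.startswith("^SUBSET"):
                current = {}
                subsets.append(current)
            elif line.startswith("!subset_"):
                key, _, val = line[len("!subset_") :].partition(" = ")
                current[key] = val
    if not table_lines:
        raise ValueError(f"no dataset table found in {path}")
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    subset_df = pd.DataFrame(subsets) if subsets else pd.DataFrame()
    return table, subset_df
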