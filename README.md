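# coexmod

Cross-condition coexpression module discovery for time-series gene
expression, by meta-analytic consensus clustering.

## The problem

A transcriptional response profiled under several conditions — different
dosing regimens, tissues, platforms, time grids — cannot be analysed by
pooling raw intensities: the measurements are not comparable across
platforms.  `coexmod` sidesteps the incompatibility by working with a
unitless statistic.  For each condition it runs a diverse ensemble of
clustering algorithms on the per-condition profiles and records, for every
gene pair, the fraction of runs assigning the pair to the same cluster —
an *agreement matrix* whose entries read as confidence of coexpression.
Averaging the per-condition gene-level matrices yields a single
cross-condition confidence matrix, from which modules are extracted.

Given a confidence level δ (default 0.7), a pair is confidently coexpressed
when its averaged agreement is ≥ δ and confidently not when ≤ 1−δ; entries
in between are ambiguous.  Discovery alternates two steps: greedily remove
the gene with the most ambiguous entries until none remain (a "clusterable"
subset), then agglomerate clusters under a complete-linkage constraint —
two clusters merge only if *every* cross pair agrees at ≥ δ.  The removed
genes are re-analysed the same way until no multi-gene cluster emerges.
Clusters are kept when their size exceeds a threshold calibrated on
resampled null data at a user p-value (default 0.05), and similar expression
patterns can optionally be merged under a homogeneity-plus-separation
objective.  A promoter module supports the downstream regulatory analysis:
conserved-region calling from alignment score profiles, motif scanning
restricted to conserved regions (including the glucocorticoid response
element half-site TGTTCT), and module-level binding-site commonality.

Audience: computational biologists analysing multi-condition time-series
expression (microarray or otherwise) who need modules that are coherent in
*every* condition, not merely in a pooled matrix.

## Worked example

```python
import coexmod as cm

spec = cm.SyntheticSpec(n_genes=120, n_classes=6, n_conditions=3,
                        n_replicates=3, noise_factor=6.0, seed=42)
ds = cm.generate_dataset(spec)
conds = [cm.ExpressionDataset(condition_id=c, values=v, timepoints=ds.timepoints,
                              probeset_ids=ds.gene_ids)
         for c, v in zip(ds.condition_ids, ds.values)]

model = cm.ConsensusModuleDiscovery(delta=0.7, p_value=0.05, n_resamples=10,
                                    random_state=0).fit(conds)
truth = {g: int(l) for g, l in zip(ds.gene_ids, ds.class_labels)}
report = cm.evaluate_recovery(model.modules_, truth)
print("suggested nc per condition:", model.nc_used_)
print("significance size cutoff:  ", model.size_cutoff_)
print("modules found:             ", model.modules_.n_clusters)
print("module sizes:              ", model.modules_.sizes)
print("genes assigned:            ", report.n_selected, "of", len(model.gene_ids_))
print("adjusted Rand index:       ", report.ari)
```

prints

```
suggested nc per condition: [6, 5, 6]
significance size cutoff:   7
modules found:              6
module sizes:               [20, 20, 20, 20, 20, 20]
genes assigned:             120 of 120
adjusted Rand index:        1.0
```

The benchmark plants 6 gene classes whose patterns differ across the three
conditions (fresh sine phases per condition) under heteroscedastic noise.
The pipeline suggests an input cluster number per condition (6, 5, 6),
calibrates a cluster-size significance threshold of 7 genes on resampled
null data, and recovers the 6 planted modules of 20 genes each; the
adjusted Rand index of 1.0 says the recovered assignment matches the
ground-truth classes perfectly on the assigned genes.

The same pipeline is exposed as a CLI:

```bash
coexmod simulate --genes 120 --classes 6 --conditions 3 --replicates 3 --seed 42 --out sim/
coexmod discover --data sim/ --delta 0.7 --pvalue 0.05 --nr 10 --seed 0 --out run/
coexmod evaluate --modules run/modules.tsv --labels sim/labels.tsv
coexmod motifs --promoters promoters.fa --scores scores.tsv --motif TGTTCT --out bed/
```

For real data, `coexmod preprocess` ANOVA-filters each condition's table,
maps probesets to gene symbols, intersects the gene lists across conditions
and re-maps each common gene to all of its surviving probesets; a reader
for GEO GDS SOFT text files is included (`coexmod.io.read_geo_soft`).

## Acceptance script

`scripts/acceptance.py` regenerates the full 400-gene, 6-class,
5-condition synthetic benchmark and recomputes, from scratch, the pipeline's
recovery statistics in three regimes: the 3-replicate regime (adjusted Rand
index on the selected domain, and the number of significant clusters), the
1-replicate regime (cluster count), and the 4-replicate regime with the
input cluster number deliberately misspecified to 7 (cluster count).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runs in a few minutes on one CPU and writes one JSON object with a value
per quantity.
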