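"""Promoter post-analysis: conserved regions, motif scans, module-level
binding-site commonality, and the glucocorticoid-response-element search.

Conserved regions are runs of bases whose per-base alignment conservation
score stays strictly above the profile mean for more than 10 consecutive
bases.  Motif scans (IUPAC consensus strings or simple position-weight
matrices) are restricted to these regions, the rationale being that
binding-site matches on evolutionarily constrained sequence are the ones
likely to be functional.  The canonical GRE half-site searched for is the
hexamer TGTTCT.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GRE_HEXAMER",
    "ScoreProfile",
    "ConservedRegionSet",
    "MotifHit",
    "read_promoters",
    "read_score_profile",
    "call_conserved_regions",
    "scan_motif",
    "scan_pwm",
    "module_commonality",
    "gre_background_rate",
    "regions_to_bed",
    "hits_to_bed",
]

GRE_HEXAMER = "TGTTCT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

MIN_REGION_LENGTH = 10  # conserved regions must be strictly longer than this


@dataclass
class ScoreProfile:
    """Per-base conservation scores along one promoter sequence."""

    promoter_id: str
    scores: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.sequence = str(self.sequence).upper()
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if self.scores.size != len(self.sequence):
            raise ValueError("scores and sequence lengths differ")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class ConservedRegionSet:
    """Disjoint 0-based half-open intervals, each longer than 10 bp."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if end - start <= MIN_REGION_LENGTH:
                raise ValueError("conserved regions must be longer than 10 bp")
            if start < prev_end:
                raise ValueError("conserved regions must be disjoint and sorted")
            prev_end = end

    def contains(self, start: int, end: int) -> bool:
        return any(s <= start and end <= e for s, e in self.intervals)


@dataclass
class MotifHit:
    position: int  # 0-based start on the forward strand
    strand: str  # '+' or '-'
    match: str


def read_promoters(path) -> dict[str, str]:
    """Promoter sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_score_profile(path, promoter_id: str, sequence: str) -> ScoreProfile:
    """Load a per-base score track from a 2-column (position, score) TSV.

    Positions are 0-based; bases without a row score 0.
    """
    tab = pd.read_csv(path, sep="\t", comment="#", header=None, names=["position", "score"])
    scores = np.zeros(len(sequence))
    pos = tab["position"].to_numpy(dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= len(sequence)):
        raise ValueError("score positions fall outside the sequence")
    scores[pos] = tab["score"].to_numpy(dtype=float)
    return ScoreProfile(promoter_id=promoter_id, scores=scores, sequence=sequence)


def call_conserved_regions(profile: ScoreProfile) -> ConservedRegionSet:
    """Maximal runs scored strictly above the profile mean, kept when longer
    than 10 bp."""
    above = profile.scores > profile.scores.mean()
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > MIN_REGION_LENGTH:
                intervals.append((start, i))
            start = None
    if start is not None and above.size - start > MIN_REGION_LENGTH:
        intervals.append((start, int(above.size)))
    return ConservedRegionSet(intervals=intervals)


def _iupac_regex(motif: str) -> re.Pattern:
    motif = motif.upper()
    bad = [c for c in motif if c not in _IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in motif {motif!r}")
    return re.compile("(?=(" + "".join(_IUPAC[c] for c in motif) + "))")


def scan_motif(
    sequence: str,
    motif: str,
    regions: ConservedRegionSet | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Occurrences of an IUPAC motif, restricted to conserved regions.

    A hit must be fully contained in one region (no restriction when
    ``regions`` is None).  Reverse-complement matches are reported at their
    forward-strand start coordinate with strand '-'.
    """
    sequence = str(sequence).upper()
    width = len(motif)
    hits: list[MotifHit] = []
    patterns = [(_iupac_regex(motif), "+")]
    if both_strands:
        patterns.append((_iupac_regex(str(Seq(motif).reverse_complement())), "-"))
    for pattern, strand in patterns:
        for m in pattern.finditer(sequence):
            start = m.start()
            if regions is None or regions.contains(start, start + width):
                hits.append(MotifHit(position=start, strand=strand, match=m.group(1)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_pwm(
    sequence: str,
    pwm: np.ndarray,
    threshold: float,
    regions: ConservedRegionSet | None = None,
    alphabet: str = "ACGT",
) -> list[MotifHit]:
    """Minimal position-weight-matrix scan (forward strand).

    ``pwm`` is a (width, 4) array of per-position base scores; windows whose
    summed score reaches ``threshold`` and (when given) lie inside a
    conserved region are reported.  This is a plain additive scorer — no
    core/matrix-similarity semantics of commercial scanners are reproduced.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != len(alphabet):
        raise ValueError("pwm must be (width, alphabet) shaped")
    sequence = str(sequence).upper()
    index = {b: i for i, b in enumerate(alphabet)}
    width = pwm.shape[0]
    hits: list[MotifHit] = []
    for start in range(len(sequence) - width + 1):
        window = sequence[start : start + width]
        if any(b not in index for b in window):
            continue
        score = sum(pwm[i, index[b]] for i, b in enumerate(window))
        if score >= threshold and (regions is None or regions.contains(start, start + width)):
            hits.append(MotifHit(position=start, strand="+", match=window))
    return hits


def module_commonality(
    gene_motifs: dict[str, set[str]], threshold: float = 0.7
) -> dict[str, float]:
    """Motifs carried by strictly more than ``threshold`` of a module's genes.

    ``gene_motifs`` maps each gene to the motif labels found on conserved
    regions of any of its alternative promoters.  Returns retained motif ->
    commonality (fraction of genes carrying it).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not gene_motifs:
        warnings.warn("empty module: no commonality to compute", stacklevel=2)
        return {}
    n = len(gene_motifs)
    counts: dict[str, int] = {}
    for motifs in gene_motifs.values():
        for m in motifs:
            counts[m] = counts.get(m, 0) + 1
    return {m: c / n for m, c in counts.items() if c / n > threshold}


def gre_background_rate(
    gene_sets: dict[str, list[str]],
    promoters_per_gene: dict[str, list[ScoreProfile]],
    motif: str = GRE_HEXAMER,
    both_strands: bool = True,
) -> dict[str, dict]:
    """Per-set fraction of genes with a conserved-region GRE hit.

    For each named gene set, counts genes for which at least one promoter
    carries the motif fully inside a conserved region.  Genes without any
    promoter are excluded from the denominator and reported.  The scan is
    conserved-region-restricted throughout.
    """
    report: dict[str, dict] = {}
    for name, genes in gene_sets.items():
        with_hit = 0
        scanned = 0
        no_promoter: list[str] = []
        for g in genes:
            profiles = promoters_per_gene.get(g, [])
            if not profiles:
                no_promoter.append(g)
                continue
            scanned += 1
            hit = any(
                scan_motif(p.sequence, motif, call_conserved_regions(p), both_strands)
                for p in profiles
            )
            with_hit += bool(hit)
        report[name] = {
            "fraction_with_hit": with_hit / scanned if scanned else float("nan"),
            "n_scanned": scanned,
            "genes_without_promoter": no_promoter,
        }
    return report


def regions_to_bed(promoter_id: str, regions: ConservedRegionSet) -> str:
    """Conserved regions as BED lines (chrom = promoter id)."""
    return "\n".join(
        f"{promoter_id}\t{s}\t{e}\tconserved_{i + 1}" for i, (s, e) in enumerate(regions.intervals)
    )


def hits_to_bed(promoter_id: str, motif: str, hits: list[MotifHit]) -> str:
    return "\n".join(
        f"{promoter_id}\t{h.position}\t{h.position + len(motif)}\t{motif}\t0\t{h.strand}"
        for h in hits
    )
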