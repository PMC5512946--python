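"""Peak classification and nearest-gene assignment.

Each peak falls into exactly one of four genomic categories, resolved in
priority order:

1. ``TSS200`` — the peak shares >=1 bp with the strand-aware window from the
   TSS to 200 bp downstream (in the direction of transcription);
2. ``UTR3`` — overlaps an annotated 3'UTR;
3. ``intragenic`` — overlaps a gene span (exons or introns) without touching
   a TSS window or 3'UTR;
4. ``intergenic`` — overlaps no gene span or TSS window.

Peaks are assigned to genes by the nearest-gene-within-5-kb rule: among
genes whose span overlaps the peak or lies within ``max_dist`` of it
(interval-gap distance, so an overlapping gene is at distance 0), the
nearest wins; ties break to the lexicographically smallest gene id.
Transposable-element rows never receive assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import AnnotationError, GeneModel, Peak, peaks_to_frame

CATEGORIES = ("TSS200", "UTR3", "intragenic", "intergenic")


def tss200_window(gene: GeneModel, width: int = 200) -> tuple[int, int]:
    """Strand-aware [TSS, TSS + width) read in the transcription direction."""
    if gene.strand == "+":
        return gene.start, gene.start + width
    return max(0, gene.end - width), gene.end


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: Peak
    gene_id: str | None
    distance: int
    category: str


class GeneIndex:
    """Interval indices over an annotation, split by feature kind.

    TE rows are indexed separately: they are excluded from both
    classification and nearest-gene candidacy.
    """

    def __init__(self, genes: Iterable[GeneModel], tss_width: int = 200):
        self.genes = {g.gene_id: g for g in genes}
        self.chroms: set[str] = {g.chrom for g in self.genes.values()}
        self._span: dict[str, IntervalTree] = {}
        self._tss: dict[str, IntervalTree] = {}
        self._utr3: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            if g.is_te:
                continue
            self._span.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            ws, we = tss200_window(g, tss_width)
            if ws < we:
                self._tss.setdefault(g.chrom, IntervalTree()).addi(ws, we, g.gene_id)
            if g.utr3 is not None:
                self._utr3.setdefault(g.chrom, IntervalTree()).addi(*g.utr3, g.gene_id)

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.chroms:
            raise AnnotationError(
                f"peak chromosome {chrom!r} absent from annotation "
                f"(annotation has: {sorted(self.chroms)})"
            )

    def classify(self, peak: Peak) -> str:
        self._check_chrom(peak.chrom)
        if self._tss.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            return "TSS200"
        if self._utr3.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            return "UTR3"
        if self._span.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            return "intragenic"
        return "intergenic"

    def assign(self, peak: Peak, max_dist: int = 5000) -> PeakGeneAssignment:
        self._check_chrom(peak.chrom)
        tree = self._span.get(peak.chrom, IntervalTree())
        # envelope query: gap <= max_dist  <=>  overlap with the peak padded
        # by max_dist + 1 on both sides (half-open arithmetic)
        hits = tree.overlap(peak.start - max_dist - 1, peak.end + max_dist + 1)
        best: tuple[int, str] | None = None
        for iv in hits:
            if iv.begin >= peak.end:
                gap = iv.begin - peak.end
            elif iv.end <= peak.start:
                gap = peak.start - iv.end
            else:
                gap = 0
            if gap > max_dist:
                continue
            key = (gap, iv.data)
            if best is None or key < best:
                best = key
        category = self.classify(peak)
        if best is None:
            return PeakGeneAssignment(peak, None, -1, category)
        return PeakGeneAssignment(peak, best[1], best[0], category)


def classify_peak(peak: Peak, genes: Sequence[GeneModel] | GeneIndex) -> str:
    """Category of one peak (see module docstring for the priority order)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.classify(peak)


def assign_peak_to_gene(
    peak: Peak, genes: Sequence[GeneModel] | GeneIndex, max_dist: int = 5000
) -> PeakGeneAssignment:
    """Nearest gene within ``max_dist`` of the peak region, or none."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.assign(peak, max_dist)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GeneIndex,
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Classify and assign every peak; the tabular currency of the pipeline.

    Returns one row per peak with columns
    ``chrom,start,end,name,mark,condition,genotype,count,breadth,
    category,gene_id,distance`` (``gene_id`` empty and ``distance`` −1 for
    unassigned peaks).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    df = peaks_to_frame(peaks)
    assignments = [index.assign(p, max_dist) for p in peaks]
    df["category"] = [a.category for a in assignments]
    df["gene_id"] = [a.gene_id or "" for a in assignments]
    df["distance"] = [a.distance for a in assignments]
    return df


def category_distribution(annotated: pd.DataFrame) -> pd.DataFrame:
    """Fraction of peaks in each genomic category, per mark.

    Fractions sum to 1 per mark.  An empty input returns an empty table.
    """
    if len(annotated) == 0:
        import logging

        logging.getLogger(__name__).warning("category_distribution: no peaks")
        return pd.DataFrame(columns=["mark", *CATEGORIES, "n_peaks"])
    rows = []
    for mark, sub in annotated.groupby("mark", sort=True):
        frac = sub["category"].value_counts(normalize=True)
        rows.append(
            {"mark": mark, **{c: float(frac.get(c, 0.0)) for c in CATEGORIES},
             "n_peaks": len(sub)}
        )
    return pd.DataFrame(rows)
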