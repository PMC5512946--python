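"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acetylseq.core_io import ExpressionRecord, GeneModel, Peak

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def three_genes() -> list[GeneModel]:
    """Two + strand genes and one − strand gene with exons/UTR annotated."""
    return [
        GeneModel("AT1G01010", "chr1", 100, 900, "+",
                  exons=((100, 400), (500, 900)), utr3=(800, 900)),
        GeneModel("AT1G01020", "chr1", 7000, 9000, "-",
                  exons=((7000, 9000),), utr3=(7000, 7200)),
        GeneModel("AT1G01030", "chr1", 20000, 23000, "+"),
    ]


@pytest.fixture
def te_annotation(three_genes) -> list[GeneModel]:
    return three_genes + [
        GeneModel("TE0001", "chr1", 40000, 41000, "+", is_te=True)
    ]


@pytest.fixture
def expr_ten() -> list[ExpressionRecord]:
    """Ten genes with distinct air RPKM 1..10."""
    return [
        ExpressionRecord(f"g{i:02d}", float(i + 1), float(i + 1))
        for i in range(10)
    ]


# ---------------------------------------------------------------------------
# brute-force oracles (all-pairs scans, no index structures)


def oracle_classify(peak: Peak, genes: list[GeneModel]) -> str:
    """Category by exhaustive scan with explicit priority order."""

    def overlaps(a0, a1, b0, b1):
        return max(a0, b0) < min(a1, b1)

    candidates = [g for g in genes if not g.is_te and g.chrom == peak.chrom]
    for g in candidates:
        ws, we = (g.start, g.start + 200) if g.strand == "+" else (max(0, g.end - 200), g.end)
        if overlaps(peak.start, peak.end, ws, we):
            return "TSS200"
    for g in candidates:
        if g.utr3 and overlaps(peak.start, peak.end, *g.utr3):
            return "UTR3"
    for g in candidates:
        if overlaps(peak.start, peak.end, g.start, g.end):
            return "intragenic"
    return "intergenic"


def oracle_assign(peak: Peak, genes: list[GeneModel], max_dist: int = 5000):
    """(gene_id, distance) by exhaustive distance scan; (None, -1) if none."""
    best = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.is_te or g.chrom != peak.chrom:
            continue
        if g.start >= peak.end:
            gap = g.start - peak.end
        elif g.end <= peak.start:
            gap = peak.start - g.end
        else:
            gap = 0
        if gap <= max_dist and (best is None or gap < best[1]):
            best = (g.gene_id, gap)
    return best if best else (None, -1)


def random_instance(rng: np.random.Generator, n_genes=50, n_peaks=100):
    """A random annotation + peak set on one chromosome for oracle checks."""
    genes = []
    cursor = int(rng.integers(0, 2000))
    for i in range(int(rng.integers(5, n_genes + 1))):
        length = int(rng.integers(200, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        utr3 = None
        if rng.random() < 0.5:
            u = int(rng.integers(50, length // 2 + 51))
            utr3 = (cursor + length - u, cursor + length) if strand == "+" else (cursor, cursor + u)
        genes.append(
            GeneModel(f"g{i:04d}", "chr1", cursor, cursor + length, strand,
                      utr3=utr3, is_te=bool(rng.random() < 0.1))
        )
        cursor += length + int(rng.integers(0, 9000))
    span_hi = cursor + 8000
    peaks = []
    for j in range(int(rng.integers(10, n_peaks + 1))):
        s = int(rng.integers(0, span_hi))
        peaks.append(Peak("chr1", s, s + int(rng.integers(50, 2000)),
                          count=int(rng.integers(0, 200)), name=f"p{j:04d}"))
    return genes, peaks
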