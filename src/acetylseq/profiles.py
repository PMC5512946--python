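"""Coverage-ratio tracks, metagene matrices and gene-vs-TE enrichment.

The metagene matrix mimics a scale-regions computation: each row is one
gene, columns are a fixed-width upstream flank, the gene body rescaled to
a fixed number of bins, and a downstream flank.  Rows of minus-strand
genes are reversed so column 0 is always the 5' end.  Body rescaling is
mean-within-segment at single-base resolution, so a constant track yields
an exactly flat profile and two genes with the same relative signal shape
give identical rows regardless of length.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AnnotationError, CoverageTrack, GeneModel
from .expression import welch_test

logger = logging.getLogger(__name__)

BODY_BINS = 100
FLANK_BP = 2000
FLANK_BINS = 20
LOG_RATIO_PSEUDOCOUNT = 0.1  # RPKM


def log2_ratio_track(
    chip: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = LOG_RATIO_PSEUDOCOUNT,
) -> CoverageTrack:
    """Per-bin log2((ChIP + eps) / (control + eps)), e.g. ChIP over IgG."""
    if chip.bin_size != control.bin_size or set(chip.data) != set(control.data):
        raise AnnotationError("chip/control track bins do not match")
    data = {}
    for chrom, vec in chip.data.items():
        ctl = control.data[chrom]
        if len(ctl) != len(vec):
            raise AnnotationError(f"{chrom}: chip/control bin count mismatch")
        data[chrom] = np.log2((vec + pseudocount) / (ctl + pseudocount))
    return CoverageTrack(data, chip.bin_size, units="log2_ratio")


def _segment_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean within n_bins near-equal contiguous segments of a 1-D array."""
    edges = np.linspace(0, len(values), n_bins + 1).round().astype(int)
    sums = np.add.reduceat(values, edges[:-1])
    widths = np.diff(edges)
    return sums / widths


def _padded_per_base(track: CoverageTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base values over [start, end), zero-padded outside the chromosome."""
    out = np.zeros(end - start)
    lo, hi = max(start, 0), min(end, track.chrom_length(chrom))
    if lo < hi:
        out[lo - start : hi - start] = track.per_base(chrom, lo, hi)
    return out


def genebody_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_bins: int = BODY_BINS,
    flank_bp: int = FLANK_BP,
    flank_bins: int = FLANK_BINS,
) -> pd.DataFrame:
    """Scale-regions metagene matrix: flank | rescaled body | flank.

    Genes shorter than ``body_bins`` bp are dropped with a warning.
    Columns are labelled ``up_0..``, ``body_0..``, ``down_0..``; rows are
    indexed by gene_id in input order.
    """
    rows, ids, dropped = [], [], 0
    for g in genes:
        if g.length < body_bins:
            dropped += 1
            continue
        left = _padded_per_base(track, g.chrom, g.start - flank_bp, g.start)
        body = track.per_base(g.chrom, g.start, g.end)
        if len(body) < g.length:  # gene runs past the track end
            body = _padded_per_base(track, g.chrom, g.start, g.end)
        right = _padded_per_base(track, g.chrom, g.end, g.end + flank_bp)
        row = np.concatenate(
            [
                _segment_means(left, flank_bins),
                _segment_means(body, body_bins),
                _segment_means(right, flank_bins),
            ]
        )
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    if dropped:
        logger.warning("genebody_matrix: dropped %d genes shorter than %d bp",
                       dropped, body_bins)
    cols = (
        [f"up_{i}" for i in range(flank_bins)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"down_{i}" for i in range(flank_bins)]
    )
    return pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"), columns=cols)


def quintile_mean_profiles(matrix: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Column means per expression quintile (rows = quintile labels)."""
    labels = matrix.index.to_series().map(strata)
    if labels.isna().any():
        missing = matrix.index[labels.isna()][:3].tolist()
        raise AnnotationError(f"rows without a quintile: {missing} ...")
    out = matrix.groupby(labels).mean()
    out.index.name = "quintile"
    if (out.index.to_series().map(lambda q: (labels == q).sum()) == 0).any():
        raise AnnotationError("empty quintile")
    return out


def genebody_means(
    track: CoverageTrack, genes: Sequence[GeneModel]
) -> pd.Series:
    """Mean track signal over each element's body (TSS to TTS)."""
    vals = {g.gene_id: track.mean(g.chrom, g.start, g.end) for g in genes}
    return pd.Series(vals, name="body_mean").sort_index()


def gene_vs_te_enrichment(
    track: CoverageTrack, annotation: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-element mean body signal for genes vs transposable elements.

    Returns a two-row summary (n, mean, median) plus the Welch-test
    p-value comparing the two distributions.
    """
    genes = [g for g in annotation if not g.is_te]
    tes = [g for g in annotation if g.is_te]
    if not tes:
        raise AnnotationError("annotation contains no TE rows")
    gvals = genebody_means(track, genes).to_numpy(float)
    tvals = genebody_means(track, tes).to_numpy(float)
    t, p = welch_test(gvals, tvals)
    return pd.DataFrame(
        [
            {"element": "gene", "n": len(gvals), "mean": gvals.mean(),
             "median": float(np.median(gvals)), "welch_p": float(p)},
            {"element": "TE", "n": len(tvals), "mean": tvals.mean(),
             "median": float(np.median(tvals)), "welch_p": float(p)},
        ]
    )
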