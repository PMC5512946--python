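"""Core record types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based, half-open internally.  BED input is native;
tabular dialects are converted at the boundary.  Chromosome names are taken
verbatim — no "chr" normalization is attempted, and a name mismatch between
annotation and peaks is raised downstream, never silently patched.

Formats handled here:

* gene/TE annotation — BED12 or a headered TSV dialect (``gene_id, chrom,
  start, end, strand, exons, utr3, is_te``);
* peaks — BED4/BED5, column 5 read as the pooled read count;
* expression — headered TSV with per-condition RPKM columns;
* coverage — fixed-bin bedGraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three histone H3 acetylation marks the pipeline analyses.
MARKS = ("K9Ac", "K14Ac", "K23Ac")
#: Treatment conditions: hydrocarbon-free air vs. 10 ppm ethylene gas.
CONDITIONS = ("air", "C2H4")
#: Wild type and the ethylene-insensitive EIN2-null mutant.
GENOTYPES = ("Col0", "ein2-5")

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Malformed annotation/peak/expression input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcription unit.

    ``start``/``end`` are the gene span in 0-based half-open coordinates.
    The TSS is ``start`` on the + strand and ``end - 1`` on the − strand;
    the TTS is the opposite end.  ``exons`` must be sorted, non-overlapping
    and contained in the span; ``utr3`` (3′UTR), when present, likewise.
    Transposable elements carry ``is_te=True`` and are excluded from
    nearest-gene assignment but kept for the gene-vs-TE comparison.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[Interval, ...] = ()
    utr3: Interval | None = None
    is_te: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise AnnotationError(f"{self.gene_id}: bad exon [{s}, {e})")
            prev_end = e
        if self.utr3 is not None:
            s, e = self.utr3
            if s < self.start or e > self.end or s >= e:
                raise AnnotationError(f"{self.gene_id}: bad 3'UTR [{s}, {e})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """One enriched interval for one mark/condition/genotype.

    ``count`` is the read count pooled over ChIP replicates (replicate
    pooling is plain summation, :func:`pool_replicates`).
    """

    chrom: str
    start: int
    end: int
    mark: str = "K9Ac"
    condition: str = "air"
    genotype: str = "Col0"
    count: int = 0
    name: str = ""
    pvalue_call: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(f"peak [{self.start}, {self.end}): empty interval")
        if self.count < 0:
            raise AnnotationError(f"peak {self.name or self.start}: negative count")

    @property
    def breadth(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene RPKM in air and ethylene, with DE call and quintile."""

    gene_id: str
    rpkm_air: float
    rpkm_eth: float
    de_call: str = "none"
    quintile: int | None = None

    def __post_init__(self) -> None:
        if self.rpkm_air < 0 or self.rpkm_eth < 0:
            raise AnnotationError(f"{self.gene_id}: negative RPKM")
        if self.de_call not in ("up", "down", "none"):
            raise AnnotationError(f"{self.gene_id}: bad DE call {self.de_call!r}")


@dataclass
class CoverageTrack:
    """Fixed-bin coverage: one signal vector per chromosome.

    Bins tile each chromosome from position 0; the last bin may be partial.
    ``units`` documents the scale ("RPKM" or "log2_ratio").
    """

    data: dict[str, np.ndarray]
    bin_size: int
    units: str = "RPKM"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise AnnotationError("bin_size must be >= 1")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)):
                raise AnnotationError(f"{chrom}: non-finite track values")
            self.data[chrom] = vec

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end), clipped to chromosome bounds."""
        if chrom not in self.data:
            raise AnnotationError(f"chromosome {chrom!r} not in track")
        start = max(0, start)
        end = min(end, self.chrom_length(chrom))
        if start >= end:
            return np.empty(0)
        vec = self.data[chrom]
        lo, hi = start // self.bin_size, (end - 1) // self.bin_size + 1
        expanded = np.repeat(vec[lo:hi], self.bin_size)
        off = start - lo * self.bin_size
        return expanded[off : off + (end - start)]

    def mean(self, chrom: str, start: int, end: int) -> float:
        vals = self.per_base(chrom, start, end)
        return float(vals.mean()) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# gene/TE annotation


def _parse_interval_list(text: str) -> tuple[Interval, ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _gene_from_tsv_row(row: pd.Series, idx: int) -> GeneModel:
    utr3 = _parse_interval_list(str(row.get("utr3", ".")))
    if len(utr3) > 1:
        raise AnnotationError(f"row {idx}: more than one 3'UTR interval")
    return GeneModel(
        gene_id=str(row["gene_id"]),
        chrom=str(row["chrom"]),
        start=int(row["start"]),
        end=int(row["end"]),
        strand=str(row["strand"]),
        exons=_parse_interval_list(str(row.get("exons", "."))),
        utr3=utr3[0] if utr3 else None,
        is_te=bool(int(row.get("is_te", 0))),
    )


def _gene_from_bed12(fields: Sequence[str], idx: int) -> GeneModel:
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    # 3'UTR = untranslated tail past the thick (coding) region, strand-aware
    utr3: Interval | None = None
    if strand == "+" and thick_end < end:
        utr3 = (thick_end, end)
    elif strand == "-" and thick_start > start:
        utr3 = (start, thick_start)
    return GeneModel(name, chrom, start, end, strand, exons=exons, utr3=utr3)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene/TE models from BED12 or the headered TSV dialect.

    Malformed rows raise :class:`AnnotationError` naming the offending
    (1-based) row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    genes: list[GeneModel] = []
    if "gene_id" in first.split():
        df = pd.read_csv(path, sep="\t", dtype=str)
        for idx, row in df.iterrows():
            try:
                genes.append(_gene_from_tsv_row(row, int(idx) + 2))
            except (AnnotationError, ValueError, KeyError) as exc:
                raise AnnotationError(f"row {int(idx) + 2}: {exc}") from exc
    else:
        with open(path) as fh:
            for idx, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) < 12:
                    raise AnnotationError(f"row {idx}: expected BED12, got {len(fields)} columns")
                try:
                    genes.append(_gene_from_bed12(fields, idx))
                except (AnnotationError, ValueError) as exc:
                    raise AnnotationError(f"row {idx}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models in the TSV dialect (round-trips with the reader)."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "exons": ",".join(f"{s}-{e}" for s, e in g.exons) or ".",
                "utr3": f"{g.utr3[0]}-{g.utr3[1]}" if g.utr3 else ".",
                "is_te": int(g.is_te),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | Path,
    mark: str = "K9Ac",
    condition: str = "air",
    genotype: str = "Col0",
) -> list[Peak]:
    """Read a BED4/BED5 peak file and attach mark/condition/genotype labels.

    Column 5, when present, is the pooled read count.  Output is sorted by
    (chrom, start); duplicated rows are retained with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks: list[Peak] = []
    seen: set[tuple] = set()
    n_dup = 0
    with open(path) as fh:
        for idx, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise AnnotationError(f"row {idx}: expected >=3 BED columns")
            name = fields[3] if len(fields) > 3 else f"peak_{idx}"
            count = int(float(fields[4])) if len(fields) > 4 else 0
            if count < 0:
                raise AnnotationError(f"row {idx}: negative count")
            key = (fields[0], fields[1], fields[2], name)
            if key in seen:
                n_dup += 1
            seen.add(key)
            try:
                peaks.append(
                    Peak(fields[0], int(fields[1]), int(fields[2]),
                         mark=mark, condition=condition, genotype=genotype,
                         count=count, name=name)
                )
            except AnnotationError as exc:
                raise AnnotationError(f"row {idx}: {exc}") from exc
    if n_dup:
        logger.warning("%s: %d duplicated peak rows retained", path, n_dup)
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (name in column 4, pooled count in column 5)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{p.count}\n")


def pool_replicates(counts: Sequence[int]) -> int:
    """Pool mapped-read counts across ChIP replicates (arithmetic sum)."""
    if len(counts) == 0:
        raise AnnotationError("need at least one replicate count")
    if any(c < 0 for c in counts):
        raise AnnotationError("negative replicate count")
    return int(sum(counts))


# ---------------------------------------------------------------------------
# expression


_EXPR_COLUMNS = ["gene_id", "rpkm_air", "rpkm_eth", "de_call", "quintile"]


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read the per-gene RPKM table (TSV with header).

    Requires ``gene_id``, ``rpkm_air`` and ``rpkm_eth`` columns; ``de_call``
    and ``quintile`` are optional.  Duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise AnnotationError(f"duplicate gene_id: {dup.iloc[0]}")
    records = []
    for _, row in df.iterrows():
        q = row.get("quintile")
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                rpkm_air=float(row["rpkm_air"]),
                rpkm_eth=float(row["rpkm_eth"]),
                de_call=str(row["de_call"]) if "de_call" in row else "none",
                quintile=None if q is None or pd.isna(q) else int(q),
            )
        )
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "rpkm_air": format(r.rpkm_air, ".6g"),
            "rpkm_eth": format(r.rpkm_eth, ".6g"),
            "de_call": r.de_call,
            "quintile": "" if r.quintile is None else r.quintile,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_EXPR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table: UTF-8, tab-separated, deterministic row order."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage tracks (fixed-bin bedGraph)


def read_bedgraph(path: str | Path, bin_size: int, units: str = "RPKM") -> CoverageTrack:
    """Read a fixed-bin bedGraph into a :class:`CoverageTrack`.

    Every interval must be bin-aligned with width ``bin_size`` (the final
    interval of a chromosome may be shorter).  Missing bins are zero-filled.
    """
    df = pd.read_csv(
        path, sep="\t", comment="t", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    data: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        n_bins = int(np.ceil(sub["end"].max() / bin_size))
        vec = np.zeros(n_bins)
        idx = sub["start"].to_numpy() // bin_size
        if np.any(sub["start"].to_numpy() % bin_size):
            raise AnnotationError(f"{chrom}: bedGraph intervals not bin-aligned")
        vec[idx] = sub["value"].to_numpy()
        data[chrom] = vec
    return CoverageTrack(data, bin_size, units)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            starts = np.arange(len(vec)) * track.bin_size
            for s, v in zip(starts, vec):
                fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{format(v, '.6g')}\n")


# ---------------------------------------------------------------------------
# frame converters (the tabular currency of the analysis modules)


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Peaks as a DataFrame with one row per peak."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name for p in peaks],
            "mark": [p.mark for p in peaks],
            "condition": [p.condition for p in peaks],
            "genotype": [p.genotype for p in peaks],
            "count": [p.count for p in peaks],
            "breadth": [p.breadth for p in peaks],
        }
    )


def expression_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "rpkm_air": [r.rpkm_air for r in records],
            "rpkm_eth": [r.rpkm_eth for r in records],
            "de_call": [r.de_call for r in records],
            "quintile": [r.quintile for r in records],
        }
    )
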