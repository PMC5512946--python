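"""Synthetic dataset generator with planted chromatin/expression structure.

The generator emulates the downstream products of a pooled ChIP-seq /
RNA-seq experiment on etiolated seedlings under air vs. ethylene, in wild
type (Col0) and the ethylene-insensitive EIN2-null mutant:

* one synthetic chromosome of genes (and a transposable-element region),
  inter-gene gaps drawn so that the 5-kb nearest-gene rule is exercised on
  both sides of its threshold;
* lognormal expression with planted up/down ethylene responses drawn
  preferentially from the upper expression quintiles;
* mark presence per gene that rises with expression quintile on a logistic
  scale, with H3K9Ac the most prevalent mark and H3K14Ac the rarest;
* Poisson peak read counts around a planted enrichment that grows with
  quintile; ethylene multiplies K14Ac/K23Ac count means by ``2**m_true``
  on up-regulated genes (and ``2**-m_true`` on down-regulated ones) while
  K9Ac count means never change between conditions;
* an air-condition K9Ac bias: future up-regulated genes carry broader,
  taller K9Ac peaks than down-regulated ones in *both* conditions, so the
  planted K9Ac differential between conditions stays exactly zero;
* coverage tracks rendered from the peak counts (counts-first generation,
  so tracks and peaks can never disagree), on a body background that is
  depleted ``te_depletion``-fold over TEs;
* ``ein2-5`` mode zeroes every ethylene effect: expression, count means
  and peak intervals are identical in distribution between conditions.

Every planted quantity is recorded in the ground truth, keyed so it joins
directly onto pipeline outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CONDITIONS,
    MARKS,
    AnnotationError,
    CoverageTrack,
    ExpressionRecord,
    GeneModel,
    Peak,
    write_bedgraph,
    write_expression,
    write_gene_table,
    write_peaks,
)
from .expression import quintile_bins


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults encode the planted study structure."""

    n_genes: int = 1000
    n_tes: int = 100
    seed: int = 0
    genotype: str = "Col0"

    # placement (bp)
    gene_length_range: tuple[int, int] = (1000, 4000)
    gap_range: tuple[int, int] = (300, 9000)  # straddles the 5-kb rule
    bin_size: int = 10

    # expression: lognormal RPKM (natural-log parameters)
    log_rpkm_mean: float = 1.0
    log_rpkm_sd: float = 1.5

    # mark presence: P(mark | quintile q) = sigmoid(b + s*(q-3))
    mark_presence_logit: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "K9Ac": (0.6, 1.0),
            "K14Ac": (-1.6, 1.2),
            "K23Ac": (-0.8, 1.1),
        }
    )

    # peak breadth (bp)
    breadth_base: dict[str, float] = field(
        default_factory=lambda: {"K9Ac": 800.0, "K14Ac": 700.0, "K23Ac": 700.0}
    )
    k9_breadth_quintile_slope: float = 150.0  # bp per quintile, K9Ac only
    breadth_noise_sd: float = 60.0

    # counts: Poisson mean = count_mean_base * (1 + slope*(q-1)) * modifiers
    count_mean_base: float = 100.0
    count_quintile_slope: float = 0.5

    # ethylene response
    de_fraction: float = 0.10
    de_up_share: float = 0.39  # up:down roughly 2:3
    de_expression_coupling: float = 1.0  # weight exp(c*(q-1)) for DE sampling
    de_fc_range: tuple[float, float] = (1.8, 4.0)
    expr_noise_log2_sd: float = 0.05
    m_true: dict[str, float] = field(
        default_factory=lambda: {"K9Ac": 0.0, "K14Ac": 1.0, "K23Ac": 1.0}
    )
    k9_preexisting_bias: float = 1.4  # K9 breadth & count factor, up vs down genes
    eth_breadth_gain: float = 1.4  # K14/K23 breadth factor on up genes in ethylene

    # track background
    genebody_rpkm: float = 2.0
    te_depletion: float = 10.0
    baseline_rpkm: float = 0.05
    element_noise_sigma: float = 0.2
    n_background_peaks: int = 20

    def __post_init__(self) -> None:
        if self.genotype not in ("Col0", "ein2-5"):
            raise AnnotationError(f"unknown genotype {self.genotype!r}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise AnnotationError("de_fraction must be in [0, 1]")
        if self.te_depletion <= 0 or self.count_mean_base < 0:
            raise AnnotationError("rates must be positive")

    @property
    def is_ethylene_insensitive(self) -> bool:
        return self.genotype == "ein2-5"


@dataclass
class GroundTruth:
    """Planted truth, joinable onto pipeline outputs by gene_id / peak name."""

    genes: pd.DataFrame  # gene_id, quintile, de_call, per-mark presence, m_true
    peaks: pd.DataFrame  # name, mark, condition, gene_id, interval, planted_mean


@dataclass
class SyntheticBundle:
    annotation: list[GeneModel]  # genes followed by TEs
    peaks: dict[tuple[str, str], list[Peak]]  # (mark, condition) -> peaks
    expression: list[ExpressionRecord]
    tracks: dict[tuple[str, str], CoverageTrack] | None
    control: CoverageTrack | None
    library_sizes: dict[tuple[str, str], float]
    truth: GroundTruth
    config: SyntheticConfig

    @property
    def genes(self) -> list[GeneModel]:
        return [g for g in self.annotation if not g.is_te]

    @property
    def tes(self) -> list[GeneModel]:
        return [g for g in self.annotation if g.is_te]


def _place_elements(cfg: SyntheticConfig, rng: np.random.Generator):
    """Lay out genes, a background-peak region, and TEs on one chromosome."""
    genes: list[GeneModel] = []
    cursor = 3000
    spans = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(*cfg.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"G{i:05d}", "chr1", cursor, cursor + length, strand)
        )
        spans.append((cursor, cursor + length))
        cursor += length + int(rng.integers(*cfg.gap_range))
    bg_intervals = []
    cursor += 6000
    for i in range(cfg.n_background_peaks):
        bg_intervals.append((cursor, cursor + 300))
        cursor += 11000
    cursor += 6000
    tes: list[GeneModel] = []
    for i in range(cfg.n_tes):
        length = int(rng.integers(500, 3000))
        tes.append(GeneModel(f"TE{i:04d}", "chr1", cursor, cursor + length, "+", is_te=True))
        cursor += length + int(rng.integers(200, 2000))
    return genes, tes, bg_intervals, cursor + 3000


def _territories(genes: Sequence[GeneModel], max_room: int = 1200):
    """Per-gene clip bounds that keep each gene's peaks strictly nearest to it."""
    bounds = []
    for i, g in enumerate(genes):
        left_gap = g.start - (genes[i - 1].end if i else 0)
        right_gap = (genes[i + 1].start if i + 1 < len(genes) else g.end + 10**6) - g.end
        left = g.start - min(max_room, max(0, (left_gap - 2) // 2))
        right = g.end + min(max_room, max(0, (right_gap - 2) // 2))
        bounds.append((left, right))
    return bounds


def _peak_interval(
    gene: GeneModel, breadth: int, bounds: tuple[int, int]
) -> tuple[int, int]:
    """A TSS-covering interval of the given breadth, clipped to the territory."""
    upstream = int(round(0.25 * breadth))
    if gene.strand == "+":
        start = gene.tss - upstream
        end = start + breadth
    else:
        end = gene.tss + upstream + 1
        start = end - breadth
    start = max(start, bounds[0])
    end = min(end, bounds[1])
    # keep the TSS covered even after clipping
    start = min(start, gene.tss)
    end = max(end, gene.tss + 1)
    return start, end


def generate(cfg: SyntheticConfig, with_tracks: bool = True) -> SyntheticBundle:
    """Draw a full dataset bundle plus ground truth; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    genes, tes, bg_intervals, chrom_len = _place_elements(cfg, rng)
    n = len(genes)
    insensitive = cfg.is_ethylene_insensitive

    # --- expression -------------------------------------------------------
    rpkm_air = rng.lognormal(cfg.log_rpkm_mean, cfg.log_rpkm_sd, size=n)
    tmp = [
        ExpressionRecord(g.gene_id, float(r), float(r))
        for g, r in zip(genes, rpkm_air)
    ]
    quintile = quintile_bins(tmp, "air")  # gene_id -> 1..5
    q_arr = np.array([quintile[g.gene_id] for g in genes])

    de_call = np.full(n, "none", dtype=object)
    if not insensitive and cfg.de_fraction > 0:
        eligible = np.flatnonzero(rpkm_air > 1.0)
        n_de = min(len(eligible), int(round(cfg.de_fraction * n)))
        weights = np.exp(cfg.de_expression_coupling * (q_arr[eligible] - 1))
        weights = weights / weights.sum()
        chosen = rng.choice(eligible, size=n_de, replace=False, p=weights)
        is_up = rng.random(n_de) < cfg.de_up_share
        de_call[chosen[is_up]] = "up"
        de_call[chosen[~is_up]] = "down"

    noise = np.power(2.0, rng.normal(0.0, cfg.expr_noise_log2_sd, size=n))
    fc = rng.uniform(*cfg.de_fc_range, size=n)
    rpkm_eth = rpkm_air * noise
    rpkm_eth[de_call == "up"] = (rpkm_air * fc)[de_call == "up"]
    rpkm_eth[de_call == "down"] = (rpkm_air / fc)[de_call == "down"]

    expression = [
        ExpressionRecord(g.gene_id, float(a), float(e))
        for g, a, e in zip(genes, rpkm_air, rpkm_eth)
    ]

    # --- mark presence ----------------------------------------------------
    presence: dict[str, np.ndarray] = {}
    for mark in MARKS:
        b, s = cfg.mark_presence_logit[mark]
        prob = np.array([_sigmoid(b + s * (q - 3)) for q in q_arr])
        presence[mark] = rng.random(n) < prob

    # --- peaks ------------------------------------------------------------
    bounds = _territories(genes)
    peaks: dict[tuple[str, str], list[Peak]] = {
        (m, c): [] for m in MARKS for c in CONDITIONS
    }
    truth_peak_rows = []
    for mark in MARKS:
        base_b = cfg.breadth_base[mark]
        m_true = 0.0 if insensitive else cfg.m_true.get(mark, 0.0)
        for i, g in enumerate(genes):
            if not presence[mark][i]:
                continue
            q = q_arr[i]
            breadth_air = base_b + cfg.breadth_noise_sd * rng.normal()
            if mark == "K9Ac":
                breadth_air += cfg.k9_breadth_quintile_slope * (q - 1)
                if de_call[i] == "up":
                    breadth_air *= cfg.k9_preexisting_bias
            breadth_air = max(100, int(round(breadth_air)))
            breadth_eth = breadth_air
            if (
                mark in ("K14Ac", "K23Ac")
                and de_call[i] == "up"
                and not insensitive
            ):
                breadth_eth = max(100, int(round(breadth_air * cfg.eth_breadth_gain)))
            mean = cfg.count_mean_base * (1 + cfg.count_quintile_slope * (q - 1))
            if mark == "K9Ac" and de_call[i] == "up":
                mean *= cfg.k9_preexisting_bias  # both conditions: no K9 change
            direction = {"up": 1.0, "down": -1.0}.get(de_call[i], 0.0)
            mean_eth = mean * 2.0 ** (m_true * direction)
            for cond, brd, mu in (
                ("air", breadth_air, mean),
                ("C2H4", breadth_eth, mean_eth),
            ):
                s, e = _peak_interval(g, brd, bounds[i])
                count = int(rng.poisson(mu))
                name = f"{mark}_{cond}_{g.gene_id}"
                peaks[(mark, cond)].append(
                    Peak("chr1", s, e, mark=mark, condition=cond,
                         genotype=cfg.genotype, count=count, name=name)
                )
                truth_peak_rows.append(
                    {"name": name, "mark": mark, "condition": cond,
                     "gene_id": g.gene_id, "start": s, "end": e,
                     "count": count, "planted_mean": mu,
                     "m_true": m_true * direction}
                )
        for j, (s, e) in enumerate(bg_intervals):
            mu = cfg.count_mean_base * 0.3
            for cond in CONDITIONS:
                count = int(rng.poisson(mu))
                name = f"{mark}_{cond}_bg{j:03d}"
                peaks[(mark, cond)].append(
                    Peak("chr1", s, e, mark=mark, condition=cond,
                         genotype=cfg.genotype, count=count, name=name)
                )
                truth_peak_rows.append(
                    {"name": name, "mark": mark, "condition": cond,
                     "gene_id": "", "start": s, "end": e,
                     "count": count, "planted_mean": mu, "m_true": 0.0}
                )
    for key in peaks:
        peaks[key].sort(key=lambda p: (p.chrom, p.start, p.end))

    library_sizes = {
        key: float(max(sum(p.count for p in plist), 1)) for key, plist in peaks.items()
    }

    # --- truth tables -----------------------------------------------------
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "quintile": q_arr,
            "de_call": de_call,
            **{mark: presence[mark] for mark in MARKS},
        }
    )
    gene_truth["state"] = [
        "+".join(m for m in MARKS if presence[m][i]) or "none" for i in range(n)
    ]
    truth = GroundTruth(genes=gene_truth, peaks=pd.DataFrame(truth_peak_rows))

    # --- tracks (rendered from the drawn counts) --------------------------
    tracks: dict[tuple[str, str], CoverageTrack] | None = None
    control: CoverageTrack | None = None
    if with_tracks:
        n_bins = int(np.ceil(chrom_len / cfg.bin_size))
        elem_noise_genes = rng.lognormal(
            -0.5 * cfg.element_noise_sigma**2, cfg.element_noise_sigma, size=n
        )
        elem_noise_tes = rng.lognormal(
            -0.5 * cfg.element_noise_sigma**2, cfg.element_noise_sigma, size=len(tes)
        )
        background = np.full(n_bins, cfg.baseline_rpkm)
        for g, w in zip(genes, elem_noise_genes):
            background[g.start // cfg.bin_size : -(-g.end // cfg.bin_size)] += (
                cfg.genebody_rpkm * w
            )
        for t, w in zip(tes, elem_noise_tes):
            background[t.start // cfg.bin_size : -(-t.end // cfg.bin_size)] += (
                cfg.genebody_rpkm / cfg.te_depletion * w
            )
        tracks = {}
        for key, plist in peaks.items():
            arr = background.copy()
            lib_m = library_sizes[key] / 1e6
            for p in plist:
                density = p.count / ((p.breadth / 1000.0) * lib_m)
                arr[p.start // cfg.bin_size : -(-p.end // cfg.bin_size)] += density
            tracks[key] = CoverageTrack({"chr1": arr}, cfg.bin_size, "RPKM")
        control = CoverageTrack({"chr1": np.ones(n_bins)}, cfg.bin_size, "RPKM")

    return SyntheticBundle(
        annotation=genes + tes,
        peaks=peaks,
        expression=expression,
        tracks=tracks,
        control=control,
        library_sizes=library_sizes,
        truth=truth,
        config=cfg,
    )


def ground_truth(bundle: SyntheticBundle) -> dict[str, pd.DataFrame]:
    """Truth tables keyed like pipeline outputs (per-gene and per-peak)."""
    return {"gene_truth": bundle.truth.genes, "peak_truth": bundle.truth.peaks}


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize the bundle in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genes"] = outdir / "annotation.tsv"
    write_gene_table(bundle.annotation, paths["genes"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(bundle.expression, paths["expression"])
    for (mark, cond), plist in sorted(bundle.peaks.items()):
        key = f"peaks_{mark}_{cond}"
        paths[key] = outdir / f"{key}.bed"
        write_peaks(plist, paths[key])
    if bundle.tracks is not None:
        for (mark, cond), track in sorted(bundle.tracks.items()):
            key = f"track_{mark}_{cond}"
            paths[key] = outdir / f"{key}.bedgraph"
            write_bedgraph(track, paths[key])
        paths["control"] = outdir / "track_control.bedgraph"
        write_bedgraph(bundle.control, paths["control"])
    paths["gene_truth"] = outdir / "gene_truth.tsv"
    bundle.truth.genes.to_csv(paths["gene_truth"], sep="\t", index=False)
    paths["peak_truth"] = outdir / "peak_truth.tsv"
    bundle.truth.peaks.to_csv(paths["peak_truth"], sep="\t", index=False)
    return paths
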