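"""End-to-end orchestration: stages, report tables, manifest, synthetic demo.

``analyze`` runs every stage for one genotype (three marks, two
conditions) on in-memory objects and returns a dict of plain DataFrames —
the numeric tables behind category distributions, state partitions and
overlaps, per-state expression statistics, breadth and TSS-enrichment
strata, MA differential tables, and metagene profiles.  ``run_all`` is the
file-driven wrapper (paths in, TSV report plus JSON manifest out);
``demo`` generates a synthetic bundle, analyses it, and joins the result
against the generator's ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import GeneIndex, annotate_peaks, category_distribution
from .core_io import (
    CONDITIONS,
    MARKS,
    AnnotationError,
    CoverageTrack,
    ExpressionRecord,
    GeneModel,
    Peak,
    expression_to_frame,
    read_bedgraph,
    read_expression,
    read_gene_table,
    read_peaks,
    write_table,
)
from .differential import differential_by_gene, differential_table, match_common_peaks
from .expression import (
    assign_de,
    breadth_by_stratum,
    expression_by_state,
    quintile_bins,
    tss_enrichment_by_stratum,
)
from .profiles import (
    gene_vs_te_enrichment,
    genebody_matrix,
    genebody_means,
    log2_ratio_track,
    quintile_mean_profiles,
)
from .simulate import SyntheticBundle, SyntheticConfig, generate
from .states import compute_states, overlap_matrix, partition

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Thresholds and windows for one pipeline run."""

    max_dist: int = 5000
    fc_threshold: float = 1.5
    rpkm_floor: float = 1.0
    m_threshold: float = 0.4
    p_threshold: float = 0.05
    density_pseudocount: float = 1.0
    trim_sigma: float | None = None
    tss_window: int = 1000
    body_bins: int = 100
    flank_bp: int = 2000
    flank_bins: int = 20
    log_pseudocount: float = 0.1

    def __post_init__(self) -> None:
        for name in ("max_dist", "fc_threshold", "rpkm_floor", "m_threshold",
                     "p_threshold", "tss_window"):
            if getattr(self, name) <= 0:
                raise AnnotationError(f"{name} must be positive")


def _cond_key(cond: str) -> str:
    return "air" if cond == "air" else "eth"


def analyze(
    annotation: Sequence[GeneModel],
    peaks: dict[tuple[str, str], list[Peak]],
    expression: Sequence[ExpressionRecord],
    tracks: dict[tuple[str, str], CoverageTrack] | None = None,
    control: CoverageTrack | None = None,
    library_sizes: dict[tuple[str, str], float] | None = None,
    params: AnalysisParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage for one genotype; returns named report tables."""
    params = params or AnalysisParams()
    t0 = time.time()
    missing = [k for m in MARKS for k in [(m, "air"), (m, "C2H4")] if k not in peaks]
    if missing:
        raise AnnotationError(f"missing peak sets for {missing}")
    index = GeneIndex(annotation)
    gene_ids = [g.gene_id for g in annotation if not g.is_te]
    report: dict[str, pd.DataFrame] = {}

    # stage 1: annotation
    annotated = {
        key: annotate_peaks(plist, index, params.max_dist)
        for key, plist in peaks.items()
    }
    logger.info("annotate: %d peaks in %d sets",
                sum(map(len, annotated.values())), len(annotated))

    # stage 2: category distributions per condition
    cat_tables = []
    for cond in CONDITIONS:
        allm = pd.concat([annotated[(m, cond)] for m in MARKS], ignore_index=True)
        tab = category_distribution(allm)
        tab.insert(0, "condition", cond)
        cat_tables.append(tab)
    report["category_distribution"] = pd.concat(cat_tables, ignore_index=True)

    # stage 3: chromatin states, partitions, overlaps (per condition)
    states = {}
    part_rows, overlap_rows = [], []
    for cond in CONDITIONS:
        allm = pd.concat([annotated[(m, cond)] for m in MARKS], ignore_index=True)
        st = compute_states(allm, gene_ids)
        states[cond] = st
        part = partition(st)
        part_rows.append(part.rename_axis("state").reset_index().assign(condition=cond))
        ov = overlap_matrix(part)
        ov.insert(0, "condition", cond)
        overlap_rows.append(ov)
        report[f"states_{_cond_key(cond)}"] = st.reset_index()
    report["state_partition"] = pd.concat(part_rows, ignore_index=True)
    report["mark_overlap"] = pd.concat(overlap_rows, ignore_index=True)

    # stage 4: expression strata
    quintiles = {
        "air": quintile_bins(expression, "air"),
        "C2H4": quintile_bins(expression, "C2H4"),
    }
    de = assign_de(expression, params.fc_threshold, params.rpkm_floor)
    expr_df = expression_to_frame(expression)
    expr_df["de_call"] = expr_df["gene_id"].map(de)
    expr_df["quintile_air"] = expr_df["gene_id"].map(quintiles["air"])
    report["expression"] = expr_df

    # stage 5: expression by chromatin state
    sum_rows, test_rows = [], []
    for cond in CONDITIONS:
        s, t = expression_by_state(states[cond], expression, condition=cond)
        s.insert(0, "condition", cond)
        t.insert(0, "condition", cond)
        sum_rows.append(s)
        test_rows.append(t)
    report["expression_by_state_summary"] = pd.concat(sum_rows, ignore_index=True)
    report["expression_by_state_tests"] = pd.concat(test_rows, ignore_index=True)

    # stage 6: breadth by quintile and by DE class
    def _breadth(strata: pd.Series, pairs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        sums, tests = [], []
        for cond in CONDITIONS:
            allm = pd.concat([annotated[(m, cond)] for m in MARKS], ignore_index=True)
            s, t = breadth_by_stratum(allm, strata, pairs)
            for df in (s, t):
                if len(df):
                    df.insert(0, "condition", cond)
            sums.append(s)
            tests.append(t)
        return (pd.concat(sums, ignore_index=True),
                pd.concat(tests, ignore_index=True))

    s, t = _breadth(quintiles["air"], pairs=[(1, 5)])
    report["breadth_by_quintile_summary"], report["breadth_by_quintile_tests"] = s, t
    s, t = _breadth(de, pairs=[("up", "down")])
    report["breadth_by_de_summary"], report["breadth_by_de_tests"] = s, t

    # stage 7: TSS-window enrichment strata (needs tracks)
    if tracks is not None:
        genes_only = [g for g in annotation if not g.is_te]
        sums, tests = [], []
        for (mark, cond), track in sorted(tracks.items()):
            s, t, _ = tss_enrichment_by_stratum(
                track, genes_only, de, params.tss_window, [("up", "down")]
            )
            for df in (s, t):
                df.insert(0, "condition", cond)
                df.insert(0, "mark", mark)
            sums.append(s)
            tests.append(t)
        report["tss_by_de_summary"] = pd.concat(sums, ignore_index=True)
        report["tss_by_de_tests"] = pd.concat(tests, ignore_index=True)

    # stage 8: MA differential enrichment per mark
    if library_sizes is None:
        library_sizes = {
            key: float(max(sum(p.count for p in plist), 1))
            for key, plist in peaks.items()
        }
    diff_tables, gene_of_pair, fit_rows = {}, {}, []
    for mark in MARKS:
        pairs, un_air, un_eth = match_common_peaks(
            peaks[(mark, "air")], peaks[(mark, "C2H4")]
        )
        if len(pairs) < 10:
            logger.warning("differential: %s has %d common peaks, skipped",
                           mark, len(pairs))
            continue
        table, fit = differential_table(
            pairs,
            library_sizes[(mark, "air")],
            library_sizes[(mark, "C2H4")],
            params.density_pseudocount,
            params.trim_sigma,
            params.m_threshold,
            params.p_threshold,
        )
        diff_tables[mark] = table
        assigned = [
            index.assign(
                Peak(p.chrom, p.start, p.end, mark=mark), params.max_dist
            ).gene_id or ""
            for p in pairs
        ]
        gene_of_pair[mark] = pd.Series(assigned)
        table["gene_id"] = assigned
        fit_rows.append(
            {"mark": mark, "b0": fit.b0, "b1": fit.b1,
             "se_b0": fit.se_b0, "se_b1": fit.se_b1,
             "n_pairs": len(pairs), "n_unmatched_air": len(un_air),
             "n_unmatched_eth": len(un_eth)}
        )
    if diff_tables:
        report["differential_peaks"] = pd.concat(
            diff_tables.values(), ignore_index=True
        )
        report["ma_fits"] = pd.DataFrame(fit_rows)
        eps = 0.01
        log2fc = pd.Series(
            {r.gene_id: float(np.log2((r.rpkm_eth + eps) / (r.rpkm_air + eps)))
             for r in expression}
        )
        report["differential_by_gene"] = differential_by_gene(
            diff_tables, gene_of_pair, de, log2fc
        )

    # stage 9: metagene profiles and gene-vs-TE enrichment (needs tracks)
    if tracks is not None:
        genes_only = [g for g in annotation if not g.is_te]
        prof_rows, gvt_rows = [], []
        for (mark, cond), track in sorted(tracks.items()):
            sig = (
                log2_ratio_track(track, control, params.log_pseudocount)
                if control is not None
                else track
            )
            mat = genebody_matrix(
                sig, genes_only, params.body_bins, params.flank_bp, params.flank_bins
            )
            prof = quintile_mean_profiles(mat, quintiles[cond])
            prof = prof.reset_index()
            prof.insert(0, "condition", cond)
            prof.insert(0, "mark", mark)
            prof_rows.append(prof)
            gvt = gene_vs_te_enrichment(track, annotation)
            gvt.insert(0, "condition", cond)
            gvt.insert(0, "mark", mark)
            gvt_rows.append(gvt)
        report["quintile_profiles"] = pd.concat(prof_rows, ignore_index=True)
        report["gene_vs_te"] = pd.concat(gvt_rows, ignore_index=True)

    logger.info("analyze: %d tables in %.1fs", len(report), time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# file-driven run


@dataclass
class RunConfig:
    """Input paths and thresholds for a file-driven run (one genotype)."""

    genes: str
    expression: str
    peaks: dict[str, dict[str, str]]  # mark -> condition -> path
    tracks: dict[str, dict[str, str]] | None = None
    control: str | None = None
    bin_size: int = 10
    genotype: str = "Col0"
    outdir: str = "acetylseq_report"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = AnalysisParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        for mark in MARKS:
            for cond in CONDITIONS:
                try:
                    p = self.peaks[mark][cond]
                except KeyError:
                    raise AnnotationError(
                        f"config missing peaks for ({mark}, {cond})"
                    ) from None
                if not Path(p).exists():
                    raise AnnotationError(f"peak file for ({mark}, {cond}) not found: {p}")
        for p in (self.genes, self.expression):
            if not Path(p).exists():
                raise AnnotationError(f"input file not found: {p}")


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Load inputs per RunConfig, run every stage, write TSVs + manifest."""
    config.validate()
    t0 = time.time()
    annotation = read_gene_table(config.genes)
    expression = read_expression(config.expression)
    peaks = {
        (mark, cond): read_peaks(config.peaks[mark][cond], mark, cond, config.genotype)
        for mark in MARKS
        for cond in CONDITIONS
    }
    tracks = None
    control = None
    if config.tracks:
        tracks = {
            (mark, cond): read_bedgraph(path, config.bin_size)
            for mark, conds in config.tracks.items()
            for cond, path in conds.items()
        }
        if config.control:
            control = read_bedgraph(config.control, config.bin_size)
    report = analyze(annotation, peaks, expression, tracks, control,
                     params=config.params)
    write_report(report, config.outdir, config=asdict(config.params),
                 elapsed=time.time() - t0)
    return report


def write_report(
    report: dict[str, pd.DataFrame],
    outdir: str | Path,
    config: dict | None = None,
    elapsed: float | None = None,
) -> Path:
    """Write every table as TSV plus a JSON manifest (versions, config hash)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "acetylseq_version": __version__,
        "tables": {},
        "config": config or {},
        "elapsed_seconds": elapsed,
    }
    for name in sorted(report):
        path = outdir / f"{name}.tsv"
        write_table(report[name], path)
        manifest["tables"][name] = {
            "rows": int(len(report[name])),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


# ---------------------------------------------------------------------------
# synthetic demo


def recovery_summary(bundle: SyntheticBundle, report: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join pipeline output against generator truth; one row per check."""
    truth = bundle.truth.genes.set_index("gene_id")
    rows = []
    for cond in CONDITIONS:
        st = report[f"states_{_cond_key(cond)}"].set_index("gene_id")
        joined = st.join(truth, rsuffix="_true")
        agree = float((joined["state"] == joined["state_true"]).mean())
        rows.append({"check": f"state_recovery_{cond}", "value": agree,
                     "n": len(joined)})
    expr = report["expression"].set_index("gene_id")
    de_joined = expr.join(truth["de_call"], rsuffix="_true")
    rows.append(
        {"check": "de_recovery",
         "value": float((de_joined["de_call"] == de_joined["de_call_true"]).mean()),
         "n": len(de_joined)}
    )
    if "differential_peaks" in report:
        for mark, sub in report["differential_peaks"].groupby("mark"):
            rows.append(
                {"check": f"differential_fraction_{mark}",
                 "value": float((sub["call"] != "unchanged").mean()),
                 "n": len(sub)}
            )
    return pd.DataFrame(rows)


def demo(
    seed: int = 0,
    outdir: str | Path | None = None,
    genotype: str = "Col0",
    n_genes: int = 300,
    with_tracks: bool = True,
) -> tuple[SyntheticBundle, dict[str, pd.DataFrame], pd.DataFrame]:
    """One-command synthetic demo: generate, analyse, compare with truth."""
    cfg = SyntheticConfig(n_genes=n_genes, seed=seed, genotype=genotype)
    bundle = generate(cfg, with_tracks=with_tracks)
    report = analyze(
        bundle.annotation, bundle.peaks, bundle.expression,
        bundle.tracks, bundle.control, bundle.library_sizes,
    )
    recovery = recovery_summary(bundle, report)
    report["truth_recovery"] = recovery
    if outdir is not None:
        write_report(report, outdir, config={"seed": seed, "genotype": genotype,
                                             "n_genes": n_genes})
    return bundle, report, recovery
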