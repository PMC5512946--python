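"""Expression stratification and mark/expression integration.

Genes are ranked by RPKM in a reference condition and split into five
equal-size quintiles (5 = highest expression).  Differential expression
between air and ethylene uses the fold-change rule: up if the
ethylene/air RPKM ratio exceeds ``fc_threshold`` and the larger RPKM
exceeds ``rpkm_floor``; down symmetrically; zero denominators get a small
RPKM pseudocount.  The per-state and per-stratum comparisons (expression by
chromatin state, peak breadth by stratum, TSS-window enrichment by
stratum) summarise distributions and report two-sided Welch t-tests, with
Benjamini–Hochberg adjusted p-values alongside the raw ones.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnnotationError,
    CoverageTrack,
    ExpressionRecord,
    GeneModel,
)

LOG2_PSEUDOCOUNT = 0.01  # RPKM added before log2 transforms
FC_PSEUDOCOUNT = 0.01  # RPKM substituted for zero denominators in fold changes


def quintile_bins(
    records: Sequence[ExpressionRecord], reference_condition: str = "air"
) -> pd.Series:
    """Assign each gene to an expression quintile (1 = lowest, 5 = highest).

    Genes are stably sorted by (RPKM in the reference condition, gene_id)
    and split into five contiguous blocks whose sizes differ by at most
    one; when n is not divisible by 5 the larger blocks sit at the higher
    quintiles.
    """
    n = len(records)
    if n < 5:
        raise AnnotationError(f"need >= 5 genes to form quintiles, got {n}")
    attr = {"air": "rpkm_air", "C2H4": "rpkm_eth", "eth": "rpkm_eth"}.get(
        reference_condition
    )
    if attr is None:
        raise AnnotationError(f"unknown reference condition {reference_condition!r}")
    order = sorted(records, key=lambda r: (getattr(r, attr), r.gene_id))
    base, extra = divmod(n, 5)
    sizes = [base + (1 if q >= 5 - extra else 0) for q in range(5)]
    out: dict[str, int] = {}
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for r in order[pos : pos + size]:
            out[r.gene_id] = q
        pos += size
    return pd.Series(out, name="quintile").sort_index()


def call_de(
    record: ExpressionRecord,
    fc_threshold: float = 1.5,
    rpkm_floor: float = 1.0,
) -> str:
    """Classify one gene as up/down/none between ethylene and air."""
    air = record.rpkm_air if record.rpkm_air > 0 else FC_PSEUDOCOUNT
    eth = record.rpkm_eth if record.rpkm_eth > 0 else FC_PSEUDOCOUNT
    if max(record.rpkm_air, record.rpkm_eth) <= rpkm_floor:
        return "none"
    if eth / air > fc_threshold:
        return "up"
    if air / eth > fc_threshold:
        return "down"
    return "none"


def assign_de(
    records: Sequence[ExpressionRecord],
    fc_threshold: float = 1.5,
    rpkm_floor: float = 1.0,
) -> pd.Series:
    """DE call for every gene, as a gene_id-indexed Series."""
    return pd.Series(
        {r.gene_id: call_de(r, fc_threshold, rpkm_floor) for r in records},
        name="de_call",
    ).sort_index()


def _label(value) -> str:
    """Canonical stratum label: integral floats print as ints."""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test robust to degenerate (zero-variance) groups.

    With no variance in either group the t statistic is undefined; the
    comparison degenerates to equality of the two constants: p = 1 when
    the means coincide, 0 when they differ.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 0.0, 1.0 if x.mean() == y.mean() else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def _welch_table(groups: Mapping[str, np.ndarray], pairs=None) -> pd.DataFrame:
    """Two-sided Welch t-tests between groups, with BH-adjusted p-values."""
    names = sorted(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        t, p = welch_test(x, y)
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
             "mean_a": float(x.mean()), "mean_b": float(y.mean()),
             "t_stat": float(t), "pvalue": float(p)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["pvalue_bh"] = stats.false_discovery_control(df["pvalue"], method="bh")
    return df


def _summary_rows(groups: Mapping[str, np.ndarray], key: str) -> pd.DataFrame:
    rows = []
    for name in sorted(groups):
        v = np.asarray(groups[name], float)
        rows.append(
            {key: name, "n": len(v),
             "median": float(np.median(v)) if len(v) else np.nan,
             "q1": float(np.percentile(v, 25)) if len(v) else np.nan,
             "q3": float(np.percentile(v, 75)) if len(v) else np.nan,
             "mean": float(v.mean()) if len(v) else np.nan}
        )
    return pd.DataFrame(rows)


def expression_by_state(
    state_table: pd.DataFrame,
    records: Sequence[ExpressionRecord],
    condition: str = "air",
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2-expression distribution per chromatin state, with pairwise tests.

    States with fewer than 2 genes are summarised but excluded from the
    Welch tests (their exclusion is visible in the summary ``n`` column).
    Returns ``(summary, tests)``.
    """
    attr = "rpkm_air" if condition == "air" else "rpkm_eth"
    rpkm = {r.gene_id: getattr(r, attr) for r in records}
    groups: dict[str, np.ndarray] = {}
    for state, sub in state_table.groupby("state"):
        vals = np.array([rpkm[g] for g in sub.index if g in rpkm], float)
        groups[state] = np.log2(vals + pseudocount)
    summary = _summary_rows(groups, "state")
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    tests = _welch_table(testable)
    return summary, tests


def breadth_by_stratum(
    annotated: pd.DataFrame,
    strata: pd.Series,
    test_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-breadth distributions per stratum per mark, with Welch tests.

    ``strata`` maps gene_id to a stratum label (quintile or DE class);
    each gene contributes the breadths of all peaks assigned to it.
    Returns ``(summary, tests)`` with a ``mark`` column in both.
    """
    assigned = annotated[annotated["gene_id"] != ""]
    summaries, tests = [], []
    for mark, sub in assigned.groupby("mark", sort=True):
        labels = sub["gene_id"].map(strata)
        groups = {
            _label(lab): grp["breadth"].to_numpy(float)
            for lab, grp in sub.groupby(labels)
            if len(grp)
        }
        if not groups:
            continue
        s = _summary_rows(groups, "stratum")
        s.insert(0, "mark", mark)
        summaries.append(s)
        testable = {k: v for k, v in groups.items() if len(v) >= 2}
        pairs = None
        if test_pairs is not None:
            pairs = [(_label(a), _label(b)) for a, b in test_pairs
                     if _label(a) in testable and _label(b) in testable]
        t = _welch_table(testable, pairs)
        t.insert(0, "mark", mark)
        tests.append(t)
    empty = pd.DataFrame()
    return (
        pd.concat(summaries, ignore_index=True) if summaries else empty,
        pd.concat(tests, ignore_index=True) if tests else empty,
    )


def tss_window(gene: GeneModel, window: int = 1000) -> tuple[int, int]:
    """Symmetric window of total width ``window`` centred on the TSS."""
    half = window // 2
    return gene.tss - half, gene.tss - half + window


def tss_enrichment_by_stratum(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    strata: pd.Series,
    window: int = 1000,
    test_pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Mean track signal in the TSS window per gene, summarised per stratum.

    Windows running past chromosome bounds are clipped.  Returns
    ``(summary, tests, per_gene_means)``.
    """
    means: dict[str, float] = {}
    for g in genes:
        if g.is_te or g.gene_id not in strata.index:
            continue
        s, e = tss_window(g, window)
        m = track.mean(g.chrom, s, e)
        if np.isfinite(m):
            means[g.gene_id] = m
    per_gene = pd.Series(means, name="tss_mean").sort_index()
    labels = per_gene.index.to_series().map(strata)
    groups = {
        _label(lab): per_gene[labels == lab].to_numpy(float)
        for lab in labels.dropna().unique()
    }
    summary = _summary_rows(groups, "stratum")
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    pairs = None
    if test_pairs is not None:
        pairs = [(_label(a), _label(b)) for a, b in test_pairs
                 if _label(a) in testable and _label(b) in testable]
    tests = _welch_table(testable, pairs)
    return summary, tests, per_gene
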