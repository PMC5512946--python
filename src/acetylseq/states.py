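"""Combinatorial chromatin states: which of {K9Ac, K14Ac, K23Ac} mark each gene.

A gene carries a mark iff at least one peak of that mark is assigned to it
by the nearest-gene rule, giving each gene one of 8 states (the 7 non-empty
mark subsets plus "none").  States are computed separately per condition and
genotype; the air wild-type partition is the usual reference.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MARKS, AnnotationError

#: Canonical state labels: subsets joined by "+", ordered K9, K14, K23.
STATE_LABELS = tuple(
    "+".join(c) for r in range(3, 0, -1) for c in combinations(MARKS, r)
) + ("none",)


def state_label(marks_present: Sequence[str]) -> str:
    present = [m for m in MARKS if m in marks_present]
    return "+".join(present) if present else "none"


def compute_states(
    annotated: pd.DataFrame, gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-gene mark-presence table from one condition/genotype's assignments.

    Parameters
    ----------
    annotated
        Output of :func:`acetylseq.annotate.annotate_peaks` for all three
        marks of a single (condition, genotype).  Mixing conditions or
        genotypes is an error.
    gene_ids
        The gene universe; genes with no assigned peak get state "none".

    Returns a DataFrame indexed by gene_id with one boolean column per mark
    plus a ``state`` label column.
    """
    if len(annotated):
        for col in ("condition", "genotype"):
            if annotated[col].nunique() > 1:
                raise AnnotationError(
                    f"mixed {col} labels in assignment input: "
                    f"{sorted(annotated[col].unique())}"
                )
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for mark in MARKS:
        sub = annotated[(annotated["mark"] == mark) & (annotated["gene_id"] != "")]
        out[mark] = out.index.isin(set(sub["gene_id"]))
    cols = [out[m].to_numpy() for m in MARKS]
    out["state"] = [
        "+".join(m for m, present in zip(MARKS, flags) if present) or "none"
        for flags in zip(*cols)
    ]
    return out


def filter_top_enriched(annotated: pd.DataFrame, quantile: float = 0.8) -> pd.DataFrame:
    """Keep peaks above the given quantile of count density (count/kb).

    The default reproduces a "top 20% enriched peaks" sensitivity
    re-analysis feeding the same state partition.
    """
    density = annotated["count"] / (annotated["breadth"] / 1000.0)
    return annotated[density >= density.quantile(quantile)].copy()


def partition(states: pd.DataFrame) -> pd.Series:
    """Counts of the 8 states; sums to the number of genes considered."""
    counts = states["state"].value_counts()
    return pd.Series(
        {lab: int(counts.get(lab, 0)) for lab in STATE_LABELS}, name="n_genes"
    )


def overlap_fraction(
    part: pd.Series, mark_a: str, mark_b: str
) -> tuple[float, int]:
    """Percent of mark_a-marked genes that also carry mark_b.

    Returns ``(unrounded_percent, rounded_percent)``; the rounded integer
    percent is the reporting convention, the unrounded value is retained.
    Raises if no gene carries mark_a.
    """
    total_a = sum(n for lab, n in part.items() if mark_a in lab.split("+"))
    both = sum(
        n for lab, n in part.items()
        if {mark_a, mark_b} <= set(lab.split("+"))
    )
    if total_a == 0:
        raise AnnotationError(f"no genes marked by {mark_a}: overlap undefined")
    pct = 100.0 * both / total_a
    return pct, int(round(pct))


def overlap_matrix(part: pd.Series) -> pd.DataFrame:
    """All ordered mark-pair overlap percentages from one partition."""
    rows = []
    for a in MARKS:
        for b in MARKS:
            if a == b:
                continue
            pct, rounded = overlap_fraction(part, a, b)
            rows.append({"mark_a": a, "mark_b": b, "percent": pct, "rounded": rounded})
    return pd.DataFrame(rows)


def pairwise_mark_correlation(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for each mark pair of per-gene enrichment.

    ``enrichment`` has genes as rows and one column per mark (gene-body
    RPKM).  Rows with a non-finite value in either mark of a pair are
    dropped for that pair; fewer than 3 finite pairs or zero variance is an
    error for that pair.
    """
    rows = []
    for a, b in combinations(MARKS, 2):
        if a not in enrichment.columns or b not in enrichment.columns:
            continue
        x = enrichment[a].to_numpy(dtype=float)
        y = enrichment[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            raise AnnotationError(f"{a} vs {b}: fewer than 3 finite gene pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise AnnotationError(f"{a} vs {b}: zero variance")
        r, p = stats.pearsonr(x, y)
        rows.append({"mark_a": a, "mark_b": b, "pearson_r": float(r),
                     "pvalue": float(p), "n_genes": len(x)})
    return pd.DataFrame(rows)
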