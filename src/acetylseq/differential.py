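"""MA-statistic differential enrichment between conditions at common peaks.

For a peak interval detected in both conditions (a *common peak*), read
densities are RPKM-style, ``(count + pseudocount) / (breadth_kb *
library_millions)``, and

    M = log2(density_eth / density_air)
    A = 0.5 * log2(density_eth * density_air)

Systematic between-library bias is removed by fitting an ordinary
least-squares line M = b0 + b1*A on the common peaks and subtracting it
(the MA normalization), leaving the rescaled M with mean zero over the
fitted peaks.  Significance per peak is an exact two-sided binomial test of
the ethylene count — rescaled onto the air scale by the fitted line —
against an even split.  Peaks with |rescaled M| >= 0.4 and p <= 0.05
(both boundaries inclusive) are called gained or lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnnotationError, Peak

M_THRESHOLD = 0.4
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class CommonPeakPair:
    """A merged interval detected in both conditions, with per-side counts."""

    chrom: str
    start: int
    end: int
    count_air: int
    count_eth: int
    mark: str = "K9Ac"
    genotype: str = "Col0"

    @property
    def breadth(self) -> int:
        return self.end - self.start


def match_common_peaks(
    peaks_air: Sequence[Peak], peaks_eth: Sequence[Peak]
) -> tuple[list[CommonPeakPair], list[Peak], list[Peak]]:
    """Pair overlapping peaks across conditions.

    Overlap means >=1 shared base.  Chains of overlaps (one peak touching
    several on the other side, or vice versa) collapse into a single pair
    spanning the union of the chain, with counts summed per side.  Returns
    ``(pairs, unmatched_air, unmatched_eth)``.
    """
    marks = {p.mark for p in peaks_air} | {p.mark for p in peaks_eth}
    genos = {p.genotype for p in peaks_air} | {p.genotype for p in peaks_eth}
    if len(marks) > 1 or len(genos) > 1:
        raise AnnotationError(
            f"common-peak matching needs one mark/genotype, got {marks}/{genos}"
        )
    tagged = [(p, "air") for p in peaks_air] + [(p, "eth") for p in peaks_eth]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    pairs: list[CommonPeakPair] = []
    unmatched: dict[str, list[Peak]] = {"air": [], "eth": []}

    def flush(cluster: list[tuple[Peak, str]]) -> None:
        sides = {side for _, side in cluster}
        if sides == {"air", "eth"}:
            p0 = cluster[0][0]
            pairs.append(
                CommonPeakPair(
                    chrom=p0.chrom,
                    start=min(p.start for p, _ in cluster),
                    end=max(p.end for p, _ in cluster),
                    count_air=sum(p.count for p, s in cluster if s == "air"),
                    count_eth=sum(p.count for p, s in cluster if s == "eth"),
                    mark=p0.mark,
                    genotype=p0.genotype,
                )
            )
        else:
            for p, side in cluster:
                unmatched[side].append(p)

    cluster: list[tuple[Peak, str]] = []
    cur_chrom, cur_end = None, -1
    for p, side in tagged:
        if p.chrom != cur_chrom or p.start >= cur_end:
            if cluster:
                flush(cluster)
            cluster, cur_chrom, cur_end = [], p.chrom, p.end
        cluster.append((p, side))
        cur_end = max(cur_end, p.end)
    if cluster:
        flush(cluster)
    return pairs, unmatched["air"], unmatched["eth"]


def read_density(
    counts: np.ndarray, breadths_bp: np.ndarray, library_size: float,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """RPKM-style density: (count + pseudocount) / (kb * million reads)."""
    breadths_bp = np.asarray(breadths_bp, float)
    if np.any(breadths_bp <= 0):
        raise AnnotationError("zero peak breadth")
    return (np.asarray(counts, float) + pseudocount) / (
        (breadths_bp / 1000.0) * (library_size / 1e6)
    )


def compute_ma(
    pairs: Sequence[CommonPeakPair],
    lib_air: float,
    lib_eth: float,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (M, A) per common peak."""
    counts_air = np.array([p.count_air for p in pairs], float)
    counts_eth = np.array([p.count_eth for p in pairs], float)
    breadths = np.array([p.breadth for p in pairs], float)
    d_air = read_density(counts_air, breadths, lib_air, pseudocount)
    d_eth = read_density(counts_eth, breadths, lib_eth, pseudocount)
    m_raw = np.log2(d_eth / d_air)
    a = 0.5 * np.log2(d_eth * d_air)
    return m_raw, a


@dataclass(frozen=True)
class MAFit:
    """OLS fit M = b0 + b1*A with standard errors and fit mask."""

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    fitted: np.ndarray  # boolean mask of pairs used in the final fit

    def predict(self, a: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(a, float)


def _ols(m: np.ndarray, a: np.ndarray) -> tuple[float, float, float, float]:
    x = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(x, m, rcond=None)
    resid = m - x @ coef
    dof = max(len(m) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return float(coef[0]), float(coef[1]), float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


def normalize_ma(
    m_raw: np.ndarray,
    a: np.ndarray,
    trim_sigma: float | None = None,
) -> tuple[np.ndarray, MAFit]:
    """Remove the fitted M-on-A trend; returns (rescaled M, fit).

    With ``trim_sigma`` set, one trimming pass drops pairs whose residual
    from the initial fit exceeds that many residual standard deviations
    before refitting.  The rescaled M has mean 0 (to ~1e-12) over the pairs
    used in the final fit.
    """
    m_raw = np.asarray(m_raw, float)
    a = np.asarray(a, float)
    if len(m_raw) < 10:
        raise AnnotationError(f"need >= 10 common peaks to normalize, got {len(m_raw)}")
    if np.ptp(a) == 0:
        raise AnnotationError("degenerate A: zero variance")
    mask = np.ones(len(a), bool)
    b0, b1, se0, se1 = _ols(m_raw, a)
    if trim_sigma is not None:
        resid = m_raw - (b0 + b1 * a)
        sd = resid.std(ddof=2)
        mask = np.abs(resid) <= trim_sigma * sd
        if mask.sum() >= 10 and np.ptp(a[mask]) > 0:
            b0, b1, se0, se1 = _ols(m_raw[mask], a[mask])
    fit = MAFit(b0, b1, se0, se1, fitted=mask)
    return m_raw - fit.predict(a), fit


def _binom_two_sided_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p vs p=0.5, vectorized.

    For the symmetric Binomial(n, 1/2) the minimum-likelihood two-sided
    p-value equals min(1, 2*min(P(X<=k), P(X>=k))).
    """
    k = np.asarray(k, int)
    n = np.asarray(n, int)
    p = np.ones(np.broadcast(k, n).shape)
    ok = n > 0
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    p = np.where(ok, np.minimum(1.0, 2.0 * np.minimum(lower, upper)), 1.0)
    return p


def pair_pvalues(
    count_air: np.ndarray,
    count_eth: np.ndarray,
    fit: MAFit,
    a: np.ndarray,
) -> np.ndarray:
    """Exact binomial p per pair after rescaling ethylene to the air scale.

    The ethylene count is multiplied by ``2**(-(b0 + b1*A))`` (the fitted
    bias at that A) and rounded; the test asks whether the rescaled
    ethylene count and the air count are an even split.  Two zero counts
    give p = 1.
    """
    count_air = np.asarray(count_air, int)
    eth_scaled = np.rint(
        np.asarray(count_eth, float) * np.power(2.0, -fit.predict(a))
    ).astype(int)
    return _binom_two_sided_half(eth_scaled, count_air + eth_scaled)


def call_differential(
    m_rescaled: np.ndarray,
    pvalues: np.ndarray,
    m_threshold: float = M_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> np.ndarray:
    """gain / loss / unchanged per pair, boundaries inclusive."""
    m = np.asarray(m_rescaled, float)
    p = np.asarray(pvalues, float)
    out = np.full(len(m), "unchanged", dtype=object)
    out[(m >= m_threshold) & (p <= p_threshold)] = "gain"
    out[(m <= -m_threshold) & (p <= p_threshold)] = "loss"
    return out


def differential_table(
    pairs: Sequence[CommonPeakPair],
    lib_air: float,
    lib_eth: float,
    pseudocount: float = 1.0,
    trim_sigma: float | None = None,
    m_threshold: float = M_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> tuple[pd.DataFrame, MAFit]:
    """One row per common peak: interval, counts, M_raw, A, M_rescaled, p, call.

    This is the numeric content of an MA/volcano plot for one mark.
    """
    m_raw, a = compute_ma(pairs, lib_air, lib_eth, pseudocount)
    m_res, fit = normalize_ma(m_raw, a, trim_sigma)
    pvals = pair_pvalues(
        np.array([p.count_air for p in pairs]),
        np.array([p.count_eth for p in pairs]),
        fit, a,
    )
    calls = call_differential(m_res, pvals, m_threshold, p_threshold)
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in pairs],
            "start": [p.start for p in pairs],
            "end": [p.end for p in pairs],
            "mark": [p.mark for p in pairs],
            "count_air": [p.count_air for p in pairs],
            "count_eth": [p.count_eth for p in pairs],
            "M_raw": m_raw,
            "A": a,
            "M_rescaled": m_res,
            "pvalue": pvals,
            "call": calls,
        }
    )
    return df, fit


def differential_by_gene(
    diff_tables: dict[str, pd.DataFrame],
    gene_of_pair: dict[str, pd.Series],
    de_calls: pd.Series,
    expr_log2fc: pd.Series,
) -> pd.DataFrame:
    """Join per-mark differential calls onto genes with their expression change.

    ``diff_tables`` maps mark -> differential table; ``gene_of_pair`` maps
    mark -> Series aligned with that table giving the assigned gene id
    ("" = unassigned).  Per gene and mark the peak with the largest
    |M_rescaled| is kept.  Genes whose peaks are all unchanged (or which
    have no peaks) are omitted.  The result is the numeric matrix behind a
    differential-enrichment-vs-expression heat map.
    """
    per_gene: dict[str, dict] = {}
    for mark, table in diff_tables.items():
        genes = gene_of_pair[mark]
        sub = table.assign(gene_id=genes.to_numpy())
        sub = sub[sub["gene_id"] != ""]
        idx = sub.groupby("gene_id")["M_rescaled"].apply(lambda s: s.abs().idxmax())
        best = sub.loc[idx.to_numpy()]
        for _, row in best.iterrows():
            g = per_gene.setdefault(row["gene_id"], {})
            g[f"M_{row['mark']}"] = row["M_rescaled"]
            g[f"call_{row['mark']}"] = row["call"]
    rows = []
    for gene_id, vals in sorted(per_gene.items()):
        calls = [v for k, v in vals.items() if k.startswith("call_")]
        if all(c == "unchanged" for c in calls):
            continue
        rows.append(
            {"gene_id": gene_id, **vals,
             "de_call": de_calls.get(gene_id, "none"),
             "expr_log2fc": float(expr_log2fc.get(gene_id, np.nan))}
        )
    return pd.DataFrame(rows)
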