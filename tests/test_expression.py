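"""Quintile stratification, DE calling, and stratum comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from acetylseq.core_io import CoverageTrack, ExpressionRecord, GeneModel
from acetylseq.expression import (
    assign_de,
    breadth_by_stratum,
    call_de,
    expression_by_state,
    quintile_bins,
    tss_enrichment_by_stratum,
    tss_window,
)
from acetylseq.core_io import AnnotationError


class TestQuintileBins:
    def test_ten_distinct_two_per_quintile(self, expr_ten):
        q = quintile_bins(expr_ten)
        sizes = q.value_counts().sort_index()
        assert sizes.tolist() == [2, 2, 2, 2, 2]
        assert q["g00"] == 1 and q["g09"] == 5  # 5 = highest expression

    def test_ties_broken_by_gene_id(self):
        records = [ExpressionRecord(f"g{i:02d}", 1.0, 1.0) for i in range(10)]
        q = quintile_bins(records)
        assert q.value_counts().tolist() == [2] * 5
        assert q["g00"] == 1 and q["g01"] == 1 and q["g09"] == 5

    def test_n7_block_sizes_larger_at_high_quintiles(self):
        records = [ExpressionRecord(f"g{i}", float(i), 0.0) for i in range(7)]
        q = quintile_bins(records)
        sizes = q.value_counts().sort_index().tolist()
        assert sizes == [1, 1, 1, 2, 2]

    def test_too_few_genes(self):
        with pytest.raises(AnnotationError):
            quintile_bins([ExpressionRecord("g", 1.0, 1.0)] * 1)

    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=5, max_size=40))
    def test_permutation_invariant_and_idempotent(self, rpkms):
        records = [ExpressionRecord(f"g{i:03d}", float(r), 0.0)
                   for i, r in enumerate(rpkms)]
        q1 = quintile_bins(records)
        q2 = quintile_bins(records[::-1])
        assert q1.equals(q2)
        assert q1.equals(quintile_bins(records))
        assert q1.value_counts().max() - q1.value_counts().min() <= 1


class TestCallDE:
    @pytest.mark.parametrize(
        "air,eth,expected",
        [
            (2.0, 3.5, "up"),      # FC 1.75 > 1.5
            (2.0, 2.5, "none"),    # FC 1.25
            (0.4, 0.9, "none"),    # RPKM floor fails
            (3.5, 2.0, "down"),
            (2.0, 3.0, "none"),    # FC exactly 1.5 is not > 1.5
            (0.0, 2.0, "up"),      # zero denominator via pseudocount
            (2.0, 0.0, "down"),
        ],
    )
    def test_rule(self, air, eth, expected):
        assert call_de(ExpressionRecord("g", air, eth)) == expected

    @given(st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False))
    def test_up_down_mutually_exclusive(self, air, eth):
        call = call_de(ExpressionRecord("g", air, eth))
        swapped = call_de(ExpressionRecord("g", eth, air))
        assert call in ("up", "down", "none")
        if call == "up":
            assert swapped == "down"
        elif call == "down":
            assert swapped == "up"

    def test_assign_de_series(self):
        records = [ExpressionRecord("a", 2.0, 3.5), ExpressionRecord("b", 2.0, 2.1)]
        de = assign_de(records)
        assert de.tolist() == ["up", "none"]


class TestExpressionByState:
    def _states(self, mapping):
        df = pd.DataFrame({"state": pd.Series(mapping)})
        df.index.name = "gene_id"
        return df

    def test_identical_groups_p_one(self):
        states = self._states({f"g{i}": ("K9Ac" if i < 4 else "none") for i in range(8)})
        records = [ExpressionRecord(f"g{i}", float(i % 4 + 1), 0.0) for i in range(8)]
        _, tests = expression_by_state(states, records)
        assert tests["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_shifted_group_strongly_detected(self):
        rng = np.random.default_rng(0)
        mapping, records = {}, []
        for i in range(100):
            g = f"g{i:03d}"
            hi = i < 50
            mapping[g] = "K9Ac+K14Ac+K23Ac" if hi else "none"
            log2 = rng.normal(4.0 if hi else 0.0, 1.0)
            records.append(ExpressionRecord(g, float(2.0 ** log2), 0.0))
        _, tests = expression_by_state(self._states(mapping), records)
        assert tests["pvalue"].iloc[0] < 1e-10

    def test_small_states_excluded_from_tests(self):
        mapping = {"g0": "K14Ac", "g1": "K9Ac", "g2": "K9Ac", "g3": "K9Ac",
                   "g4": "none", "g5": "none"}
        records = [ExpressionRecord(g, 1.0 + i, 0.0)
                   for i, g in enumerate(sorted(mapping))]
        summary, tests = expression_by_state(self._states(mapping), records)
        assert summary.set_index("state").loc["K14Ac", "n"] == 1
        tested = set(tests["group_a"]) | set(tests["group_b"])
        assert "K14Ac" not in tested


class TestBreadthByStratum:
    def _annot(self, breadths_by_gene):
        rows = []
        for g, breadths in breadths_by_gene.items():
            for b in breadths:
                rows.append({"mark": "K9Ac", "gene_id": g, "breadth": b,
                             "condition": "air", "genotype": "Col0", "count": 1})
        return pd.DataFrame(rows)

    def test_identical_strata_p_one(self):
        annot = self._annot({"g1": [100, 200, 300], "g2": [100, 200, 300]})
        strata = pd.Series({"g1": "up", "g2": "down"})
        _, tests = breadth_by_stratum(annot, strata, [("up", "down")])
        assert tests["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_doubled_breadths_double_median(self):
        annot = self._annot({"g1": [100, 200, 400], "g2": [200, 400, 800]})
        strata = pd.Series({"g1": "down", "g2": "up"})
        summary, _ = breadth_by_stratum(annot, strata)
        med = summary.set_index("stratum")["median"]
        assert med["up"] == 2 * med["down"]


class TestTssEnrichment:
    def test_minus_strand_window_coordinates(self):
        gene = GeneModel("g", "chr1", 1000, 2000, "-")
        assert tss_window(gene, 1000) == (1499, 2499)

    def test_uniform_track_equal_strata(self):
        track = CoverageTrack({"chr1": np.full(1000, 2.0)}, bin_size=10)
        genes = [GeneModel(f"g{i}", "chr1", 1000 + i * 2000, 2500 + i * 2000, "+")
                 for i in range(4)]
        strata = pd.Series({"g0": "up", "g1": "up", "g2": "down", "g3": "down"})
        summary, tests, _ = tss_enrichment_by_stratum(track, genes, strata)
        assert summary["mean"].nunique() == 1
        assert tests["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_signal_only_in_up_windows_detected(self):
        rng = np.random.default_rng(1)
        n = 50
        genes, vec, strata = [], np.zeros(40000), {}
        for i in range(2 * n):
            start = 2000 + i * 150
            g = GeneModel(f"g{i:03d}", "chr1", start * 10 // 10, start + 120, "+")
            genes.append(g)
            up = i < n
            strata[g.gene_id] = "up" if up else "down"
            if up:
                lo, hi = (start - 50) // 10, (start + 50) // 10
                vec[lo:hi] = 5.0 + rng.normal(0, 0.1)
        track = CoverageTrack({"chr1": vec}, bin_size=10)
        _, tests, _ = tss_enrichment_by_stratum(
            track, genes, pd.Series(strata), window=100, test_pairs=[("up", "down")]
        )
        row = tests.iloc[0]
        assert row["mean_a"] < row["mean_b"] if row["group_a"] == "down" else \
            row["mean_a"] > row["mean_b"]
        assert row["pvalue"] < 0.01

    def test_window_clipped_at_chromosome_start(self):
        track = CoverageTrack({"chr1": np.full(100, 1.0)}, bin_size=10)
        gene = GeneModel("g", "chr1", 100, 600, "+")
        strata = pd.Series({"g": "up"})
        _, _, per_gene = tss_enrichment_by_stratum(track, [gene], strata, window=1000)
        assert per_gene["g"] == pytest.approx(1.0)
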