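"""Common-peak matching, MA statistics, normalization, p-values, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acetylseq.core_io import AnnotationError, Peak
from acetylseq.differential import (
    CommonPeakPair,
    call_differential,
    compute_ma,
    differential_by_gene,
    differential_table,
    match_common_peaks,
    normalize_ma,
    pair_pvalues,
    _binom_two_sided_half,
)


def _peak(start, end, count, cond="air"):
    return Peak("chr1", start, end, condition=cond, count=count)


class TestMatchCommonPeaks:
    def test_overlapping_pair_merged(self):
        pairs, ua, ue = match_common_peaks(
            [_peak(100, 300, 40)], [_peak(250, 450, 60, "C2H4")]
        )
        assert len(pairs) == 1 and not ua and not ue
        p = pairs[0]
        assert (p.start, p.end, p.count_air, p.count_eth) == (100, 450, 40, 60)

    def test_disjoint_unmatched(self):
        pairs, ua, ue = match_common_peaks(
            [_peak(100, 200, 10)], [_peak(300, 400, 10, "C2H4")]
        )
        assert not pairs and len(ua) == 1 and len(ue) == 1

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        pairs, ua, ue = match_common_peaks(
            [_peak(100, 200, 10)], [_peak(200, 300, 10, "C2H4")]
        )
        assert not pairs

    def test_chain_merged_with_summed_counts(self):
        # one air peak overlapping two ethylene peaks: union-find oracle on
        # the toy overlap graph gives a single component
        pairs, ua, ue = match_common_peaks(
            [_peak(100, 500, 50)],
            [_peak(50, 150, 20, "C2H4"), _peak(400, 600, 30, "C2H4")],
        )
        assert len(pairs) == 1
        assert (pairs[0].start, pairs[0].end) == (50, 600)
        assert (pairs[0].count_air, pairs[0].count_eth) == (50, 50)

    def test_mixed_mark_rejected(self):
        with pytest.raises(AnnotationError):
            match_common_peaks(
                [Peak("chr1", 0, 10, mark="K9Ac")],
                [Peak("chr1", 0, 10, mark="K14Ac", condition="C2H4")],
            )


class TestComputeMA:
    def test_equal_densities_m_zero(self):
        pair = CommonPeakPair("chr1", 0, 1000, 50, 50)
        m, a = compute_ma([pair], 1e6, 1e6)
        assert m[0] == pytest.approx(0.0)

    def test_closed_form(self):
        # densities 4 and 1: breadth 1 kb, lib 1e6, counts 3 and 0 (+1 pc)
        pair = CommonPeakPair("chr1", 0, 1000, 0, 3)
        m, a = compute_ma([pair], 1e6, 1e6)
        assert m[0] == pytest.approx(2.0)
        assert a[0] == pytest.approx(1.0)

    def test_swapping_conditions_negates_m_keeps_a(self):
        rng = np.random.default_rng(0)
        pairs = [
            CommonPeakPair("chr1", i * 2000, i * 2000 + 800,
                           int(rng.integers(1, 200)), int(rng.integers(1, 200)))
            for i in range(30)
        ]
        swapped = [CommonPeakPair(p.chrom, p.start, p.end, p.count_eth, p.count_air)
                   for p in pairs]
        m1, a1 = compute_ma(pairs, 2e6, 3e6)
        m2, a2 = compute_ma(swapped, 3e6, 2e6)
        np.testing.assert_allclose(m2, -m1)
        np.testing.assert_allclose(a2, a1)


class TestNormalizeMA:
    def test_centered_input_identity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 2, 500)
        m = rng.normal(0, 0.2, 500)
        m = m - np.polyval(np.polyfit(a, m, 1), a)  # exactly centered
        m_res, fit = normalize_ma(m, a)
        np.testing.assert_allclose(m_res, m, atol=1e-9)
        assert fit.b0 == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_offset_and_slope(self):
        rng = np.random.default_rng(2)
        n = 2000
        a = rng.normal(5, 2, n)
        m = 0.7 + 0.2 * a + rng.normal(0, 0.3, n)
        m_res, fit = normalize_ma(m, a)
        assert abs(fit.b0 - 0.7) < 2 * fit.se_b0
        assert abs(fit.b1 - 0.2) < 2 * fit.se_b1
        assert abs(m_res[fit.fitted].mean()) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5, 2, 300)
        m = 0.5 + 0.1 * a + rng.normal(0, 0.3, 300)
        m1, _ = normalize_ma(m, a)
        m2, fit2 = normalize_ma(m1, a)
        np.testing.assert_allclose(m2, m1, atol=1e-9)
        assert fit2.b0 == pytest.approx(0.0, abs=1e-9)
        assert fit2.b1 == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_a_rejected(self):
        with pytest.raises(AnnotationError, match="degenerate"):
            normalize_ma(np.zeros(20), np.full(20, 3.0))

    def test_too_few_pairs(self):
        with pytest.raises(AnnotationError):
            normalize_ma(np.zeros(5), np.arange(5.0))


class TestPairPvalues:
    def _fit(self):
        from acetylseq.differential import MAFit

        return MAFit(0.0, 0.0, 0.0, 0.0, np.ones(1, bool))

    def test_balanced_counts_p_one(self):
        p = pair_pvalues([50], [50], self._fit(), np.zeros(1))
        assert p[0] == pytest.approx(1.0)

    def test_extreme_imbalance(self):
        p = pair_pvalues([10], [90], self._fit(), np.zeros(1))
        # oracle: exact binomial tail
        expect = sps.binomtest(90, 100, 0.5).pvalue
        assert p[0] == pytest.approx(expect, rel=1e-9)
        assert p[0] < 1e-10

    def test_both_zero_p_one(self):
        p = pair_pvalues([0], [0], self._fit(), np.zeros(1))
        assert p[0] == 1.0

    def test_vectorized_matches_scipy_binomtest(self):
        ks = np.arange(0, 41)
        n = 40
        ours = _binom_two_sided_half(ks, np.full_like(ks, n))
        theirs = [sps.binomtest(int(k), n, 0.5).pvalue for k in ks]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_normalization_factor_rescales_eth(self):
        from acetylseq.differential import MAFit

        # fitted bias of exactly 1 log2 unit: eth count halved before testing
        fit = MAFit(1.0, 0.0, 0.0, 0.0, np.ones(1, bool))
        p_biased = pair_pvalues([50], [100], fit, np.zeros(1))
        assert p_biased[0] == pytest.approx(1.0)


class TestCallDifferential:
    @pytest.mark.parametrize(
        "m,p,expected",
        [
            (0.4, 0.05, "gain"),      # boundary inclusive on both thresholds
            (0.39, 0.001, "unchanged"),
            (-1.2, 0.003, "loss"),
            (-0.4, 0.05, "loss"),
            (2.0, 0.051, "unchanged"),
        ],
    )
    def test_threshold_rule(self, m, p, expected):
        assert call_differential(np.array([m]), np.array([p]))[0] == expected


class TestDifferentialTable:
    def _pairs(self, rng, n=2000, mean=100.0, planted=None):
        pairs = []
        for i in range(n):
            mu_eth = mean * (planted[i] if planted is not None else 1.0)
            pairs.append(
                CommonPeakPair("chr1", i * 3000, i * 3000 + 1000,
                               int(rng.poisson(mean)), int(rng.poisson(mu_eth)))
            )
        return pairs

    def test_null_called_fraction_bounded(self):
        rng = np.random.default_rng(11)
        table, _ = differential_table(self._pairs(rng), 1e6, 1e6)
        assert (table["call"] != "unchanged").mean() <= 0.06

    def test_antisymmetry_of_calls(self):
        rng = np.random.default_rng(12)
        planted = np.ones(2000)
        planted[:200] = 2.0
        pairs = self._pairs(rng, planted=planted)
        swapped = [CommonPeakPair(p.chrom, p.start, p.end, p.count_eth, p.count_air)
                   for p in pairs]
        t1, _ = differential_table(pairs, 1e6, 1e6)
        t2, _ = differential_table(swapped, 1e6, 1e6)
        np.testing.assert_allclose(t2["M_raw"], -t1["M_raw"], atol=1e-12)
        np.testing.assert_allclose(t2["M_rescaled"], -t1["M_rescaled"], atol=1e-12)
        flip = {"gain": "loss", "loss": "gain", "unchanged": "unchanged"}
        agree = (t2["call"] == t1["call"].map(flip)).mean()
        # the binomial test rescales the ethylene side only, so pairs whose
        # p-value sits at the 0.05 boundary can flip under relabelling;
        # everything away from the boundary must swap exactly
        assert agree >= 0.98
        confident = (t1["pvalue"] < 0.01) | (t1["pvalue"] > 0.2)
        assert (t2["call"][confident] == t1["call"][confident].map(flip)).all()


class TestDifferentialByGene:
    def test_join_and_exclusion(self):
        diff = pd.DataFrame(
            {"mark": ["K14Ac", "K14Ac"], "M_rescaled": [1.2, 0.1],
             "call": ["gain", "unchanged"], "chrom": "chr1",
             "start": [0, 100], "end": [50, 150]}
        )
        tables = {"K14Ac": diff}
        gene_of_pair = {"K14Ac": pd.Series(["gA", "gB"])}
        de = pd.Series({"gA": "up", "gB": "none"})
        fc = pd.Series({"gA": 1.5, "gB": 0.0})
        out = differential_by_gene(tables, gene_of_pair, de, fc)
        assert out["gene_id"].tolist() == ["gA"]  # unchanged-only gene omitted
        row = out.iloc[0]
        assert row["call_K14Ac"] == "gain" and row["de_call"] == "up"
        assert row["expr_log2fc"] == pytest.approx(1.5)
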