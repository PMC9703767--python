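from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossregulome.core import GeneRecord, GenomeLayout, SignalTrack
from crossregulome.diff import (RegionCounts, benjamini_hochberg,
                                build_count_matrix, define_gene_sets,
                                differential_regions, exact_ratio_test,
                                rank_sum_test)


def binom_pvalue_oracle(a, b, sa=1, sb=1):
    """Exact-rational enumeration of the conditional binomial test."""
    n = a + b
    if n == 0:
        return 1.0
    pi = Fraction(sa, sa + sb)
    pmf = [Fraction(comb(n, k)) * pi ** k * (1 - pi) ** (n - k)
           for k in range(n + 1)]
    return float(sum(p for p in pmf if p <= pmf[a]))


class TestExactRatioTest:
    def test_balanced_counts_give_one(self):
        assert exact_ratio_test(10, 10) == 1.0

    def test_extreme_split(self):
        # 2 * 0.5**16 by symmetric enumeration
        assert exact_ratio_test(0, 16) == pytest.approx(2 * 0.5 ** 16, rel=1e-9)

    def test_scale_ratio_invariance(self):
        assert exact_ratio_test(5, 5, 1, 1) == exact_ratio_test(5, 5, 2, 2)

    def test_zero_total(self):
        assert exact_ratio_test(0, 0) == 1.0

    @pytest.mark.parametrize("scales", [(1, 1), (1, 2)])
    def test_matches_enumeration_oracle(self, scales):
        for n in range(0, 21):
            for a in range(n + 1):
                got = exact_ratio_test(a, n - a, *scales)
                want = binom_pvalue_oracle(a, n - a, *scales)
                assert got == pytest.approx(want, abs=1e-12), (a, n - a, scales)

    def test_super_uniform_under_null(self):
        rng = np.random.default_rng(4)
        n = 200
        draws = rng.binomial(n, 0.5, size=2_000)
        ps = np.array([exact_ratio_test(int(a), n - int(a)) for a in
                       np.unique(draws)])
        pmap = dict(zip(np.unique(draws), ps))
        pvals = np.array([pmap[a] for a in draws])
        for alpha in (0.01, 0.05, 0.2):
            assert (pvals <= alpha).mean() <= alpha + 0.02


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        got = benjamini_hochberg(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        want = np.empty(m)
        prev = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, ps[i] * m / rank)
            want[i] = prev
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestCountMatrix:
    @pytest.fixture()
    def setup(self):
        layout = GenomeLayout(("chr1",), (100_000,))
        genes = [GeneRecord("A", "chr1", 10_000, 20_000, "+"),
                 GeneRecord("B", "chr1", 40_000, 50_000, "-")]
        return layout, genes

    def _tracks(self, layout, per_bin_by_sample):
        out = {}
        for smp, (plus_val, minus_val) in per_bin_by_sample.items():
            plus = SignalTrack.zeros(layout, 100, strand="+", dtype=np.float64)
            minus = SignalTrack.zeros(layout, 100, strand="-", dtype=np.float64)
            plus.data["chr1"][:] = plus_val
            minus.data["chr1"][:] = minus_val
            out[smp] = (plus, minus)
        return out

    def test_low_count_filter_requires_all_samples(self, setup):
        layout, genes = setup
        samples = ["s1", "s2", "s3", "s4"]
        tracks = {}
        for i, smp in enumerate(samples):
            plus = SignalTrack.zeros(layout, 100, strand="+", dtype=np.float64)
            minus = SignalTrack.zeros(layout, 100, strand="-", dtype=np.float64)
            plus.data["chr1"][110:114] = 1.0      # gene A body: 4 reads everywhere
            if smp == "s3":
                minus.data["chr1"][420:426] = 1.0  # gene B body: 6 reads, s3 only
            tracks[smp] = (plus, minus)
        rc = build_count_matrix(tracks, genes,
                                {s: "untreated" for s in samples},
                                {s: 1.0 for s in samples})
        # A has < 5 reads in ALL samples -> dropped; B reaches 5 in one -> kept
        assert list(rc.counts.index) == ["B"]
        assert rc.counts.loc["B"].tolist() == [0, 0, 6, 0]

    def test_strand_specific_counting(self, setup):
        layout, genes = setup
        tracks = self._tracks(layout, {"s1": (2.0, 0.0)})
        rc = build_count_matrix(tracks, genes, {"s1": "untreated"},
                                {"s1": 1.0}, min_total=1)
        # + gene A counts only the plus track; - gene B sees nothing
        assert rc.counts.at["A", "s1"] > 0
        assert "B" not in rc.counts.index


class TestDifferentialRegions:
    def _counts(self, data):
        df = pd.DataFrame(data, index=[f"r{i}" for i in range(len(data))],
                          columns=["untreated_r1", "untreated_r2",
                                   "depleted_r1", "depleted_r2"])
        conditions = {"untreated_r1": "untreated", "untreated_r2": "untreated",
                      "depleted_r1": "depleted", "depleted_r2": "depleted"}
        scales = {s: 1.0 for s in conditions}
        return RegionCounts(counts=df, conditions=conditions,
                            scale_factors=scales)

    def test_identical_counts_are_ns(self):
        res = differential_regions(self._counts([[50, 50, 50, 50]]))
        assert res.iloc[0]["status"] == "ns"
        assert res.iloc[0]["log2FC"] == 0.0

    def test_planted_fourfold_is_up(self):
        res = differential_regions(self._counts([[50, 50, 200, 200]]))
        assert res.iloc[0]["status"] == "up"

    def test_replicate_relabeling_invariance(self):
        a = self._counts([[40, 60, 150, 250], [10, 12, 11, 9]])
        b = self._counts([[60, 40, 250, 150], [12, 10, 9, 11]])
        ra = differential_regions(a)
        rb = differential_regions(b)
        pd.testing.assert_frame_equal(ra, rb)

    def test_missing_condition_raises(self):
        df = pd.DataFrame({"s1": [5]}, index=["r0"])
        rc = RegionCounts(counts=df, conditions={"s1": "untreated"},
                          scale_factors={"s1": 1.0})
        with pytest.raises(ValueError, match="condition"):
            differential_regions(rc)


class TestGeneSets:
    def _df(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_conjunction_rules(self):
        chip = self._df([
            {"gene_id": "a", "status": "up", "log2FC": 1.5},
            {"gene_id": "b", "status": "up", "log2FC": 1.5},
            {"gene_id": "c", "status": "ns", "log2FC": 0.05},
            {"gene_id": "d", "status": "ns", "log2FC": 0.5},
        ])
        pro = self._df([
            {"gene_id": "a", "status": "up", "log2FC": 2.0},
            {"gene_id": "b", "status": "ns", "log2FC": 0.2},
            {"gene_id": "c", "status": "ns", "log2FC": -0.03},
            {"gene_id": "d", "status": "ns", "log2FC": 0.4},
        ])
        gs = define_gene_sets(chip, pro, {"a", "b", "c", "d"})
        assert set(gs.genebody_up) == {"a"}
        # b is up in ChIP only -> excluded from every set
        assert "b" not in gs.genebody_up | gs.genebody_unaffected | \
            gs.unchanged_control
        assert set(gs.unchanged_control) == {"c"}
        assert set(gs.genebody_unaffected) == {"d"}

    def test_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(200)]
        statuses = rng.choice(["up", "down", "ns"], size=(2, 200))
        lfcs = rng.normal(0, 1, size=(2, 200))
        chip = self._df([{"gene_id": g, "status": s, "log2FC": l}
                         for g, s, l in zip(ids, statuses[0], lfcs[0])])
        pro = self._df([{"gene_id": g, "status": s, "log2FC": l}
                        for g, s, l in zip(ids, statuses[1], lfcs[1])])
        gs = define_gene_sets(chip, pro, set(ids))
        assert not gs.genebody_up & gs.genebody_unaffected
        assert not gs.genebody_up & gs.unchanged_control
        assert not gs.genebody_unaffected & gs.unchanged_control


class TestRankSum:
    def test_separated_samples_exact(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_all_tied_returns_one(self):
        _, p = rank_sum_test([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = np.array([rank_sum_test(rng.normal(size=30),
                                     rng.normal(size=30))[1]
                       for _ in range(500)])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01
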