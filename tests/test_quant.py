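import numpy as np
import pytest

from crossregulome.core import GeneRecord, GenomeLayout, SignalTrack
from crossregulome.quant import (classify_active_genes,
                                 feature_distance_profile, metagene_profile,
                                 pausing_index, region_density,
                                 spike_in_scale_factors,
                                 transcription_rate_ratio)

from conftest import make_track


@pytest.fixture()
def layout():
    return GenomeLayout(("chr1",), (200_000,))


def uniform_track(layout, per_bin, bin_size=10, strand="."):
    t = SignalTrack.zeros(layout, bin_size, strand=strand, dtype=np.float64)
    for c in t.data:
        t.data[c][:] = per_bin
    return t


class TestSpikeFactors:
    def test_definitional(self):
        assert spike_in_scale_factors({"a": 1e6, "b": 2e6}) == {"a": 1.0, "b": 0.5}

    def test_equal_counts_identity(self):
        assert set(spike_in_scale_factors({"a": 5, "b": 5, "c": 5}).values()) == {1.0}

    def test_three_samples(self):
        f = spike_in_scale_factors({"a": 4e5, "b": 5e5, "c": 1e6})
        assert (f["a"], f["b"], f["c"]) == (1.0, 0.8, 0.4)

    def test_zero_count_raises(self):
        with pytest.raises(ValueError, match="cannot calibrate"):
            spike_in_scale_factors({"a": 1e6, "b": 0})


class TestRegionDensity:
    def test_reads_per_kb(self, layout):
        t = make_track(layout, bin_size=10, chr1=[0.02] * 500)
        # 10 reads over 5000 bp -> 2 reads/kb
        assert region_density(t, "chr1", 0, 5000) == pytest.approx(2.0)

    def test_empty_region_signal(self, layout):
        t = make_track(layout, bin_size=10, chr1=[0])
        assert region_density(t, "chr1", 50_000, 60_000) == 0.0

    def test_hand_computed(self, layout):
        t = make_track(layout, bin_size=10, chr1=[3, 1, 0, 4])
        assert region_density(t, "chr1", 0, 40) == pytest.approx(200.0)

    def test_off_chromosome_raises(self, layout):
        t = make_track(layout, bin_size=10, chr1=[1])
        with pytest.raises(ValueError, match="off chromosome"):
            region_density(t, "chr1", 190_000, 210_000)


class TestActivityFilter:
    def _tracks(self, layout, promoter_reads, body_per_bin):
        plus = SignalTrack.zeros(layout, 10, strand="+", dtype=np.float64)
        minus = SignalTrack.zeros(layout, 10, strand="-", dtype=np.float64)
        gene = GeneRecord("G", "chr1", 10_000, 18_000, "+")
        arr = plus.data["chr1"]
        arr[1000:1030] = 0  # promoter window bins: 9970..10300
        if promoter_reads:
            arr[999] = promoter_reads  # one bin inside [tss-30, tss+300)
        arr[1030:1800] = body_per_bin
        return plus, minus, gene

    def test_zero_promoter_is_inactive(self, layout):
        plus, minus, gene = self._tracks(layout, 0, 10)
        assert classify_active_genes(plus, minus, [gene]) == set()

    def test_body_density_just_above_threshold(self, layout):
        # body 7700 bp with total ~0.385 reads -> 0.05 reads/kb > 0.04
        plus, minus, gene = self._tracks(layout, 1, 0.385 / 770)
        assert classify_active_genes(plus, minus, [gene]) == {"G"}

    def test_body_density_below_threshold(self, layout):
        plus, minus, gene = self._tracks(layout, 1, 0.2 / 770)
        assert classify_active_genes(plus, minus, [gene]) == set()


class TestPausingIndex:
    def test_uniform_density_gives_one(self, layout):
        t = uniform_track(layout, 5)
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "+")
        assert pausing_index(t, t, gene) == pytest.approx(1.0)

    def test_hand_computed_ratio(self, layout):
        plus = SignalTrack.zeros(layout, 10, dtype=np.float64)
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "+")
        arr = plus.data["chr1"]
        arr[997:1030] = 2.0   # promoter [9970, 10300): 0.2 reads/bp
        arr[1030:2000] = 1.0  # body [10300, 20000): 0.1 reads/bp
        assert pausing_index(plus, plus, gene) == pytest.approx(2.0)

    def test_short_gene_excluded(self, layout):
        t = uniform_track(layout, 5)
        gene = GeneRecord("G", "chr1", 10_000, 14_000, "+")
        assert np.isnan(pausing_index(t, t, gene))

    def test_zero_body_undefined(self, layout):
        t = make_track(layout, bin_size=10, chr1=[0])
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "+")
        assert np.isnan(pausing_index(t, t, gene))

    def test_invariant_under_global_rescaling(self, layout):
        rng = np.random.default_rng(0)
        t = SignalTrack.zeros(layout, 10, dtype=np.float64)
        t.data["chr1"][:] = rng.poisson(2.0, len(t.data["chr1"]))
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "-")
        assert pausing_index(t, t, gene) == pytest.approx(
            pausing_index(t.scaled(7.3), t.scaled(7.3), gene))


class TestRateRatio:
    def test_equal_densities(self, layout):
        t = uniform_track(layout, 5)
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "+")
        assert transcription_rate_ratio(t, t, t, gene) == pytest.approx(1.0)

    def test_pseudocount_arithmetic(self, layout):
        pro = uniform_track(layout, 0.02)   # 2.0 reads/kb
        chip = uniform_track(layout, 0.01)  # 1.0 reads/kb
        gene = GeneRecord("G", "chr1", 10_000, 20_000, "+")
        assert transcription_rate_ratio(pro, pro, chip, gene) == \
            pytest.approx(2.01 / 1.01, rel=1e-6)


class TestCalibrationInvariance:
    def test_scaling_track_and_spike_cancels(self, layout):
        rng = np.random.default_rng(1)
        t = SignalTrack.zeros(layout, 10, dtype=np.float64)
        t.data["chr1"][:] = rng.poisson(3.0, len(t.data["chr1"]))
        t.spike_in_reads = 10_000
        c = 3.7
        t2 = t.scaled(c)
        t2.spike_in_reads = t.spike_in_reads * c
        f = spike_in_scale_factors({"ref": 10_000, "a": t.spike_in_reads,
                                    "b": t2.spike_in_reads})
        d1 = region_density(t.scaled(f["a"]), "chr1", 0, 5000)
        d2 = region_density(t2.scaled(f["b"]), "chr1", 0, 5000)
        assert d1 == pytest.approx(d2)


class TestMetagene:
    def test_constant_track_flat_profile(self, layout):
        t = uniform_track(layout, 2.0)
        genes = [GeneRecord("G", "chr1", 50_000, 60_000, "+")]
        prof = metagene_profile(t, genes, mode="scaled")
        assert prof.shape == (100 + 2 * 60,)
        np.testing.assert_allclose(prof, 2.0, rtol=1e-6)

    def test_tss_step_orientation(self, layout):
        t = SignalTrack.zeros(layout, 10, dtype=np.float64)
        t.data["chr1"][5000:] = 3.0  # step up at 50 kb
        genes = [GeneRecord("G", "chr1", 50_000, 60_000, "+")]
        prof = metagene_profile(t, genes, mode="tss_centered", flank=3000,
                                winsor=0.0)
        assert np.allclose(prof[:60], 0.0)
        assert np.allclose(prof[60:], 3.0)

    def test_strand_flip_invariance(self, layout):
        rng = np.random.default_rng(2)
        vals = rng.poisson(4.0, 2000)
        plus = SignalTrack.zeros(layout, 10, dtype=np.float64)
        plus.data["chr1"][4000:6000] = vals
        gplus = GeneRecord("G", "chr1", 45_000, 55_000, "+")
        # mirror the signal around the gene midpoint for a minus-strand twin
        minus = SignalTrack.zeros(layout, 10, dtype=np.float64)
        minus.data["chr1"][4000:6000] = vals[::-1]
        gminus = GeneRecord("G", "chr1", 45_000, 55_000, "-")
        p1 = metagene_profile(plus, [gplus], mode="scaled", winsor=0.0)
        p2 = metagene_profile(minus, [gminus], mode="scaled", winsor=0.0)
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_scaled_mode_length_invariance(self, layout):
        # same shape at lengths L and 2L -> identical scaled profiles
        def track_and_gene(length):
            t = SignalTrack.zeros(layout, 10, dtype=np.float64)
            start = 50_000
            nbins = length // 10
            ramp = np.linspace(1, 3, nbins)
            t.data["chr1"][start // 10:start // 10 + nbins] = ramp
            return t, GeneRecord("G", "chr1", start, start + length, "+")

        t1, g1 = track_and_gene(10_000)
        t2, g2 = track_and_gene(20_000)
        p1 = metagene_profile(t1, [g1], mode="scaled", winsor=0.0)
        p2 = metagene_profile(t2, [g2], mode="scaled", winsor=0.0)
        np.testing.assert_allclose(p1[60:160], p2[60:160], rtol=0.02)


class TestFeatureDistanceProfile:
    def test_no_features_all_zero(self):
        genes = [GeneRecord("G", "chr1", 50_000, 60_000, "+")]
        prof = feature_distance_profile(genes, [])
        assert prof.shape == (400,) and not prof.any()

    def test_feature_at_every_tss(self):
        genes = [GeneRecord(f"g{i}", "chr1", 30_000 * (i + 1),
                            30_000 * (i + 1) + 8_000, "+") for i in range(4)]
        feats = [(g.chrom, g.tss) for g in genes]
        prof = feature_distance_profile(genes, feats)
        assert prof[200] == pytest.approx(1.0)
        assert prof.sum() == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        genes = [GeneRecord(f"g{i}", "chr1", int(s), int(s) + 5_000,
                            "+" if i % 2 else "-")
                 for i, s in enumerate(rng.integers(20_000, 400_000, 20))]
        feats = [("chr1", int(p)) for p in rng.integers(0, 450_000, 200)]
        prof = feature_distance_profile(genes, feats, half_window=10_000, bin=50)
        expected = np.zeros(400)
        for g in genes:
            for chrom, pos in feats:
                rel = pos - g.tss
                if g.strand == "-":
                    rel = -rel
                if -10_000 <= rel < 10_000:
                    expected[(rel + 10_000) // 50] += 1
        np.testing.assert_allclose(prof, expected / len(genes))
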