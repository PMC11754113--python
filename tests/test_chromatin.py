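import numpy as np
import pandas as pd
import pytest

from tcellcircuits import chromatin as ch
from tcellcircuits import synthdata as sd
from tcellcircuits.io_formats import CoverageTrack, GeneModel


def uniform_track(value=2.0, end=120_000, contig="chrT"):
    return CoverageTrack(pd.DataFrame(
        {"contig": [contig], "start": [0], "end": [end], "value": [float(value)]}))


class TestSpikeInFactor:
    def test_equal_ratios_give_unity(self):
        assert ch.spikein_factor(ch.SpikeInCounts(100, 10, 200, 20)) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        c = ch.SpikeInCounts(9_000_000, 300_000, 8_000_000, 400_000)
        assert ch.spikein_factor(c) == pytest.approx(1.5)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="input_spike"):
            ch.spikein_factor(ch.SpikeInCounts(100, 10, 200, 0))

    def test_scaling_divides_by_factor(self):
        track = uniform_track(3.0, end=100)
        c = ch.SpikeInCounts(9_000_000, 300_000, 8_000_000, 400_000)
        scaled = ch.scale_track(track, c)
        assert scaled.data["value"].iloc[0] == pytest.approx(2.0)


class TestPeakCalling:
    def test_treatment_equals_background_gives_no_peaks(self, toy_models):
        cfg = sd.CoverageSimConfig(models=toy_models, reads=50_000, seed=1)
        chip, _, _, _ = sd.simulate_coverage(cfg)
        ps = ch.call_peaks_vs_background(chip, chip)
        assert len(ps.peaks) == 0

    def test_planted_enrichment_recovered(self, toy_models):
        # strong promoter-proximal enrichment vs uniform input: every TSS
        # window should sit inside a called peak
        cfg = sd.CoverageSimConfig(models=toy_models,
                                   target_pi={m.gene: 10.0 for m in toy_models},
                                   reads=100_000, seed=2)
        chip, inp, _, _ = sd.simulate_coverage(cfg)
        ps = ch.call_peaks_vs_background(chip, inp, contigs=["chrT"])
        assert len(ps.peaks) > 0
        for m in toy_models:
            covering = ((ps.peaks["start"] < m.tss + 200) &
                        (ps.peaks["end"] > m.tss - 200))
            assert covering.any(), m.gene

    def test_scale_invariance(self, toy_models):
        cfg = sd.CoverageSimConfig(models=toy_models,
                                   target_pi={m.gene: 8.0 for m in toy_models},
                                   reads=60_000, seed=3)
        chip, inp, _, _ = sd.simulate_coverage(cfg)
        a = ch.call_peaks_vs_background(chip, inp)
        b = ch.call_peaks_vs_background(chip.scale(2.0), inp.scale(2.0))
        pd.testing.assert_frame_equal(a.peaks, b.peaks)

    def test_empty_background_rejected(self, toy_models):
        cfg = sd.CoverageSimConfig(models=toy_models, reads=1000, seed=4)
        chip, _, _, _ = sd.simulate_coverage(cfg)
        empty = CoverageTrack(pd.DataFrame(
            {"contig": pd.Series(dtype=str), "start": pd.Series(dtype=int),
             "end": pd.Series(dtype=int), "value": pd.Series(dtype=float)}))
        with pytest.raises(ValueError, match="background"):
            ch.call_peaks_vs_background(chip, empty)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


class TestSegmentRegions:
    def test_under_threshold_unchanged(self):
        out = ch.segment_regions([peaks_df([("chr1", 0, 3000)])])
        assert out.values.tolist() == [["chr1", 0, 3000]]

    def test_greedy_split_of_long_region(self):
        out = ch.segment_regions([peaks_df([("chr1", 0, 12_000)])])
        assert [(s, e) for _, s, e in out.itertuples(index=False)] == [
            (0, 5000), (5000, 10_000), (10_000, 12_000)]

    def test_union_then_split(self):
        out = ch.segment_regions([peaks_df([("chr1", 0, 3000), ("chr1", 2000, 6000)])])
        assert [(s, e) for _, s, e in out.itertuples(index=False)] == [
            (0, 5000), (5000, 6000)]

    def test_output_covers_exactly_the_union(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 100_000, 40)
        rows = [("chr1", int(s), int(s + rng.integers(100, 9000))) for s in starts]
        out = ch.segment_regions([peaks_df(rows)])
        covered = set()
        for _, s, e in out.itertuples(index=False):
            assert e - s <= 5000
            span = set(range(s, e))
            assert not span & covered          # disjoint
            covered |= span
        expected = set()
        for _, s, e in rows:
            expected |= set(range(s, e))
        assert covered == expected


class TestNearestTss:
    def two_gene_models(self):
        return [GeneModel(gene="alpha", contig="chr1", strand="+", exons=[(1000, 3000)]),
                GeneModel(gene="beta", contig="chr1", strand="+", exons=[(9000, 12_000)])]

    def test_region_overlapping_tss_distance_zero(self):
        regions = peaks_df([("chr1", 900, 1100)])
        ann = ch.nearest_tss(regions, self.two_gene_models())
        assert ann.loc[0, "nearest_gene"] == "alpha"
        assert ann.loc[0, "tss_distance"] == 0

    def test_equidistant_tie_resolves_lexicographically_and_flags(self):
        # midpoint 5000 is 4000 from both TSSs (1000 and 9000)
        regions = peaks_df([("chr1", 4900, 5100)])
        ann = ch.nearest_tss(regions, self.two_gene_models())
        assert ann.loc[0, "nearest_gene"] == "alpha"
        assert bool(ann.loc[0, "tss_tie"])

    def test_deterministic_under_model_permutation(self):
        regions = peaks_df([("chr1", 4900, 5100), ("chr1", 8000, 8400)])
        a = ch.nearest_tss(regions, self.two_gene_models())
        b = ch.nearest_tss(regions, self.two_gene_models()[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestDifferentialRegions:
    def test_identical_groups_give_no_significant_regions(self):
        rng = np.random.default_rng(6)
        regions = peaks_df([("chr1", i * 1000, i * 1000 + 800) for i in range(25)])
        base = rng.poisson(50, size=(25, 3))
        counts = pd.DataFrame(np.hstack([base, base]),
                              index=[f"chr1:{i * 1000}-{i * 1000 + 800}" for i in range(25)],
                              columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        rm = ch.RegionMatrix(regions=regions, counts=counts)
        group = pd.Series(["ctrl"] * 3 + ["ko"] * 3, index=counts.columns)
        donor = pd.Series(["D1", "D2", "D3"] * 2, index=counts.columns)
        de, ann = differential = ch.differential_regions(rm, group, ("ko", "ctrl"), donor)
        assert (de.table["padj"] > 0.9).all()

    def test_non_integer_counts_rejected(self):
        regions = peaks_df([("chr1", 0, 800)])
        counts = pd.DataFrame({"a": [1.5], "b": [2.0]}, index=["chr1:0-800"])
        rm = ch.RegionMatrix(regions=regions, counts=counts)
        group = pd.Series(["ctrl", "ko"], index=["a", "b"])
        with pytest.raises(ValueError, match="integer"):
            ch.differential_regions(rm, group, ("ko", "ctrl"))


class TestPausingIndex:
    def test_uniform_coverage_gives_pi_exactly_one(self, toy_models):
        pt = ch.pausing_index(uniform_track(3.0), toy_models)
        assert (pt.table["pi"] == 1.0).all()

    def test_direct_formula(self):
        # TSS total 4000 over 400 bp vs body 2000 over 2000 bp -> PI = 10
        m = GeneModel(gene="gX", contig="chr1", strand="+", exons=[(10_000, 11_600)])
        # TSS window [9800, 10200): density 10; body [10400, 12000): density 1
        df = pd.DataFrame({
            "contig": ["chr1", "chr1"],
            "start": [9800, 10_400],
            "end": [10_200, 12_000],
            "value": [10.0, 1.25],
        })
        track = CoverageTrack(df)
        pt = ch.pausing_index(track, [m])
        tss_cov = 400 * 10.0
        body_cov = 1600 * 1.25
        expected = (tss_cov / 400) / (body_cov / 1600)
        assert pt.table.loc["gX", "pi"] == pytest.approx(expected)
        assert expected == pytest.approx(8.0)

    def test_zero_body_coverage_flagged_not_zero(self):
        m = GeneModel(gene="gX", contig="chr1", strand="+", exons=[(10_000, 11_600)])
        df = pd.DataFrame({"contig": ["chr1"], "start": [9800], "end": [10_200],
                           "value": [5.0]})
        pt = ch.pausing_index(CoverageTrack(df), [m])
        assert bool(pt.table.loc["gX", "flagged"])
        assert np.isnan(pt.table.loc["gX", "pi"])

    def test_rescaling_invariance(self, toy_models):
        cfg = sd.CoverageSimConfig(models=toy_models,
                                   target_pi={m.gene: 3.0 for m in toy_models},
                                   reads=50_000, seed=7)
        chip, _, _, _ = sd.simulate_coverage(cfg)
        a = ch.pausing_index(chip, toy_models).table["pi"]
        b = ch.pausing_index(chip.scale(11.0), toy_models).table["pi"]
        assert np.allclose(a, b)

    def test_minus_strand_windows_mirror(self):
        plus = GeneModel(gene="p", contig="chr1", strand="+", exons=[(10_000, 13_000)])
        minus = GeneModel(gene="m", contig="chr1", strand="-", exons=[(10_000, 13_000)])
        # put signal downstream of the minus-strand TSS (at 13,000): its TSS
        # window is [12800, 13200) and body [9600, 12600)
        df = pd.DataFrame({"contig": ["chr1"], "start": [12_800], "end": [13_200],
                           "value": [4.0]})
        track = CoverageTrack(df)
        pt = ch.pausing_index(track, [minus])
        assert bool(pt.table.loc["m", "flagged"])  # body has no coverage
        assert pt.table.loc["m", "tss_cov"] == pytest.approx(1600.0)

    def test_configured_pi_recovered(self, toy_models):
        cfg = sd.CoverageSimConfig(models=toy_models,
                                   target_pi={m.gene: 4.0 for m in toy_models},
                                   reads=100_000, seed=8)
        chip, _, _, _ = sd.simulate_coverage(cfg)
        pt = ch.pausing_index(chip, toy_models)
        med = pt.table["pi"].median()
        assert abs(med - 4.0) / 4.0 <= 0.25

    def test_expressed_filter_flag(self, toy_models):
        pt = ch.pausing_index(uniform_track(1.0), toy_models,
                              expressed={"gene0", "gene1"})
        assert pt.table["expressed"].sum() == 2
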