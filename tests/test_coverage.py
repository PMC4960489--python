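"""Depth profiling and coverage statistics."""

import numpy as np
import pytest
from scipy import stats

import plastoseq as ps
from plastoseq.coverage import (DepthProfile, log10_track, summarize_coverage,
                                unmapped_regions)
from plastoseq.genome import Feature, FeatureClass
from plastoseq.mapping import GenomeIndex


def _alnset(alns, L, stranded=False):
    return ps.AlignmentSet(alignments=alns, n_input_reads=len(alns),
                           n_mapped=len(alns), reference_length=L, stranded=stranded)


class TestComputeDepth:
    def test_no_alignments_all_zero(self):
        prof = ps.compute_depth(_alnset([], 1_000), 1_000)
        assert prof.combined().sum() == 0

    def test_single_read_footprint(self):
        aln = ps.Alignment("r1", 0, "+", 0, 100)
        prof = ps.compute_depth(_alnset([aln], 1_000), 1_000)
        d = prof.combined()
        assert (d[:100] == 1).all() and (d[100:] == 0).all()

    def test_wraparound_footprint(self):
        aln = ps.Alignment("r1", 950, "+", 0, 100)
        prof = ps.compute_depth(_alnset([aln], 1_000), 1_000)
        d = prof.combined()
        assert (d[950:] == 1).all() and (d[:50] == 1).all() and d[100:950].sum() == 0

    def test_depth_conservation_random_alignments(self):
        rng = np.random.default_rng(3)
        L = 5_000
        alns = [ps.Alignment(f"r{i}", int(rng.integers(L)),
                             "+" if rng.random() < 0.5 else "-", 0,
                             int(rng.integers(30, 120)))
                for i in range(10_000)]
        prof = ps.compute_depth(_alnset(alns, L), L, stranded=True)
        assert prof.total_bases() == sum(a.length for a in alns)

    def test_out_of_range_alignment_rejected(self):
        with pytest.raises(ValueError):
            ps.compute_depth(_alnset([ps.Alignment("r", 1_000, "+", 0, 50)], 1_000), 1_000)

    def test_monotonicity_adding_alignments(self):
        rng = np.random.default_rng(4)
        L = 2_000
        alns = [ps.Alignment(f"r{i}", int(rng.integers(L)), "+", 0, 50)
                for i in range(200)]
        prev = 0.0
        for n in (10, 50, 100, 200):
            prof = ps.compute_depth(_alnset(alns[:n], L), L)
            frac = ps.coverage_fraction(prof)
            assert frac >= prev
            prev = frac


class TestCoverageFraction:
    def test_all_zero_profile(self):
        prof = ps.compute_depth(_alnset([], 100), 100)
        assert ps.coverage_fraction(prof) == 0.0

    def test_fully_covered(self):
        prof = DepthProfile(np.ones(100, dtype=int), np.zeros(100, dtype=int), False)
        assert ps.coverage_fraction(prof) == 1.0

    def test_half_covered(self):
        d = np.zeros(100, dtype=int)
        d[:50] = 3
        prof = DepthProfile(d, np.zeros(100, dtype=int), False)
        assert ps.coverage_fraction(prof) == 0.5

    def test_mask_excludes_positions(self):
        d = np.zeros(100, dtype=int)
        d[:50] = 1
        prof = DepthProfile(d, np.zeros(100, dtype=int), False)
        mask = np.zeros(100, dtype=bool)
        mask[50:] = True                      # mask exactly the uncovered half
        assert ps.coverage_fraction(prof, mask) == 1.0

    def test_full_mask_rejected(self):
        prof = DepthProfile(np.ones(10, dtype=int), np.zeros(10, dtype=int), False)
        with pytest.raises(ValueError):
            ps.coverage_fraction(prof, np.ones(10, dtype=bool))


class TestPerClassDepthStats:
    def _plastome(self):
        return ps.Plastome(sequence="A" * 1_000,
                           features=[Feature(FeatureClass.CDS, 0, 500, "+", "g1")])

    def test_uniform_depth_quantiles_collapse(self):
        prof = DepthProfile(np.full(1_000, 4, dtype=int), np.zeros(1_000, dtype=int), False)
        out = ps.per_class_depth_stats(prof, self._plastome())
        for cls in ("CDS", "NonCDS"):
            s = out[cls].log2_summary
            assert s["median"] == s["q1"] == s["q3"] == pytest.approx(2.0)

    def test_log2_median_difference(self):
        d = np.full(1_000, 2, dtype=int)
        d[:500] = 8                            # CDS depth 8, NonCDS depth 2
        prof = DepthProfile(d, np.zeros(1_000, dtype=int), False)
        out = ps.per_class_depth_stats(prof, self._plastome())
        assert (out["CDS"].log2_summary["median"]
                - out["NonCDS"].log2_summary["median"]) == pytest.approx(2.0)

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 100, size=1_000)
        prof = DepthProfile(d, np.zeros(1_000, dtype=int), False)
        out = ps.per_class_depth_stats(prof, self._plastome())
        cds = d[:500]
        logd = np.log2(cds[cds >= 1])
        assert out["CDS"].log2_summary["median"] == pytest.approx(np.quantile(logd, 0.5))
        assert out["CDS"].log2_summary["p95"] == pytest.approx(np.quantile(logd, 0.95))
        assert out["CDS"].n_zero == int((cds == 0).sum())

    def test_every_position_in_exactly_one_class(self, small_plastome):
        prof = DepthProfile(np.ones(small_plastome.length, dtype=int),
                            np.zeros(small_plastome.length, dtype=int), False)
        out = ps.per_class_depth_stats(prof, small_plastome)
        assert (out["CDS"].n_positions + out["NonCDS"].n_positions
                == small_plastome.length)

    def test_log10_track_consistent_with_log2_source(self):
        d = np.array([0, 1, 10, 100])
        prof = DepthProfile(d, np.zeros(4, dtype=int), False)
        track = log10_track(prof)
        assert np.isnan(track[0])
        assert track[1:] == pytest.approx([0.0, 1.0, 2.0])


class TestUnmappedRegions:
    def _profile(self, d):
        return DepthProfile(np.asarray(d, dtype=int), np.zeros(len(d), dtype=int), False)

    def test_fully_covered_empty_list(self):
        intervals, hist = unmapped_regions(self._profile(np.ones(100)))
        assert intervals == [] and hist == {"lt30": 0, "ge30": 0}

    def test_single_gap(self):
        d = np.ones(100)
        d[10:20] = 0
        intervals, hist = unmapped_regions(self._profile(d))
        assert intervals == [(10, 20)]
        assert hist == {"lt30": 1, "ge30": 0}

    def test_random_gaps_match_rle_oracle(self):
        rng = np.random.default_rng(6)
        d = (rng.random(2_000) < 0.7).astype(int)
        intervals, hist = unmapped_regions(self._profile(d))
        # run-length-encoding oracle
        expected = []
        start = None
        for i, v in enumerate(d):
            if v == 0 and start is None:
                start = i
            elif v != 0 and start is not None:
                expected.append((start, i))
                start = None
        if start is not None:
            expected.append((start, len(d)))
        assert intervals == expected
        assert sum(e - s for s, e in intervals) == int((d == 0).sum())


class TestStrandCoverage:
    def test_plus_only_reads_give_zero_rev_fraction(self):
        alns = [ps.Alignment(f"r{i}", i * 100, "+", 0, 100) for i in range(5)]
        prof = ps.compute_depth(_alnset(alns, 1_000, stranded=True), 1_000, stranded=True)
        sc = ps.strand_coverage(prof)
        assert sc.rev_fraction == 0.0 and sc.fwd_fraction == 0.5

    def test_unstranded_profile_rejected(self):
        prof = DepthProfile(np.ones(10, dtype=int), np.zeros(10, dtype=int), False)
        with pytest.raises(ValueError):
            ps.strand_coverage(prof)

    def test_symmetric_simulation_balanced(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000, antisense_fraction=0.5)
        tx = ps.simulate_transcripts(small_plastome, model, n=1_000, seed=30)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=10_000, error_rate=0.0,
                                        stranded=True, seed=31)
        aln = ps.map_reads(reads, GenomeIndex(small_plastome.sequence))
        n_fwd = sum(a.strand == "+" for a in aln.alignments)
        lo, hi = stats.binom.interval(0.999, aln.n_mapped, 0.5)
        assert lo <= n_fwd <= hi

    def test_antisense_depth_uses_opposite_strand(self):
        gene = Feature(FeatureClass.CDS, 100, 200, "-", "g1")
        fwd = np.zeros(1_000, dtype=int)
        fwd[100:200] = 7                      # + strand reads over a - strand gene
        prof = DepthProfile(fwd, np.zeros(1_000, dtype=int), True)
        anti = ps.antisense_depth(prof, gene)
        assert (anti == 7).all()


class TestSummarizeCoverage:
    def test_report_fields_on_simulation(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        tx = ps.simulate_transcripts(small_plastome, model, n=800, seed=32)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=8_000, error_rate=0.0, seed=33)
        aln = ps.map_reads(reads, GenomeIndex(small_plastome.sequence))
        prof = ps.compute_depth(aln, small_plastome.length)
        report = summarize_coverage(prof, small_plastome, aln)
        assert 0.9 <= report.covered_fraction <= 1.0
        assert report.mapped_read_proportion == aln.n_mapped / 8_000
        gap_total = sum(e - s for s, e in report.unmapped_intervals)
        assert gap_total == int((prof.combined() == 0).sum())

    def test_repeat_masking_recovers_coverage(self):
        # the repeat-rich scenario: unique mapping leaves repeat interiors
        # uncovered; masking them restores near-complete coverage
        g = ps.generate_plastome(ps.GenomeSpec(length=30_000, n_genes=8,
                                               repeat_fraction=0.2), seed=9)
        model = ps.uniform_tss_model(g, spacing=2_000)
        tx = ps.simulate_transcripts(g, model, n=1_500, seed=34)
        reads = ps.transcripts_to_reads(tx, genome_length=g.length,
                                        n_reads=30_000, error_rate=0.0, seed=35)
        aln = ps.map_reads(reads, GenomeIndex(g.sequence))
        prof = ps.compute_depth(aln, g.length)
        raw = ps.coverage_fraction(prof)
        masked = ps.coverage_fraction(prof, g.repeat_mask_array())
        assert raw < masked
        assert masked >= 0.99
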