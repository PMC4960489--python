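"""Transcription simulator: length law, editing, fragmentation, ground truth."""

import numpy as np
import pytest
from scipy import stats

import plastoseq as ps
from plastoseq.simulate import EditingSiteSpec, TranscriptionModel, Tss


def _model(p, tss=None, **kw):
    return TranscriptionModel(tss_list=tss or [Tss(0, "+")],
                              per_base_termination_prob=p, **kw)


class TestSimulateTranscripts:
    def test_forced_termination_gives_length_one(self, small_plastome):
        tx = ps.simulate_transcripts(small_plastome, _model(1.0), n=50, seed=1)
        assert all(t.length == 1 for t in tx)

    def test_no_termination_reaches_length_cap(self, small_plastome):
        tx = ps.simulate_transcripts(small_plastome, _model(1e-9), n=20, seed=1,
                                     max_length=5_000)
        assert all(t.length == 5_000 for t in tx)

    def test_geometric_mean_length(self, small_plastome):
        # analytic geometric mean 1/p vs Monte-Carlo at n=10^4
        p = 0.01
        tx = ps.simulate_transcripts(small_plastome, _model(p), n=10_000, seed=2)
        mean = np.mean([t.length for t in tx])
        assert abs(mean - 1 / p) / (1 / p) < 0.05

    def test_length_distribution_is_geometric(self, small_plastome):
        # chi-square against equal-probability bins of the geometric law
        # (a KS test is miscalibrated on a discrete lattice)
        p = 0.01
        tx = ps.simulate_transcripts(small_plastome, _model(p), n=10_000, seed=3)
        lengths = np.array([t.length for t in tx])
        edges = stats.geom(p).ppf(np.linspace(0, 1, 21))
        edges[0], edges[-1] = 0, np.inf
        observed, _ = np.histogram(lengths, bins=edges)
        probs = np.diff(stats.geom(p).cdf(np.where(np.isinf(edges), 1e9, edges)))
        res = stats.chisquare(observed, probs / probs.sum() * len(lengths))
        assert res.pvalue > 0.01

    def test_transcript_sequence_matches_genome(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        L = small_plastome.length
        for t in ps.simulate_transcripts(small_plastome, model, n=50, seed=4):
            expected = "".join(small_plastome.sequence[t.genomic_position(i, L)]
                               for i in range(min(t.length, 200)))
            got = t.sequence[:min(t.length, 200)]
            if t.strand == "-":
                expected = "".join(ps.revcomp(small_plastome.sequence[t.genomic_position(i, L)])
                                   for i in range(min(t.length, 200)))
            assert got == expected

    def test_terminator_site_stops_elongation(self, small_plastome):
        from plastoseq.simulate import TerminatorSite
        model = TranscriptionModel(
            tss_list=[Tss(100, "+")], per_base_termination_prob=1e-6,
            terminator_sites=[TerminatorSite(position=600, strand="+", efficiency=1.0)])
        tx = ps.simulate_transcripts(small_plastome, model, n=30, seed=5,
                                     max_length=5_000)
        assert all(t.length == 500 for t in tx)

    def test_model_without_tss_rejected(self):
        with pytest.raises(ValueError):
            TranscriptionModel(tss_list=[], per_base_termination_prob=0.1)


class TestApplyEditing:
    def _site_on_c(self, plastome, efficiency):
        pos = plastome.sequence.index("C", 500)
        return EditingSiteSpec(position=pos, strand="+", efficiency=efficiency)

    def test_full_efficiency_edits_every_covering_transcript(self, small_plastome):
        site = self._site_on_c(small_plastome, 1.0)
        model = _model(1e-4, tss=[Tss(site.position - 100, "+")],
                       editing_sites=[site])
        tx = ps.simulate_transcripts(small_plastome, model, n=1_000, seed=6)
        covering = [t for t in tx if t.length > 100]
        assert covering
        assert all(site.position in t.edited_positions for t in covering)
        for t in covering:
            assert t.sequence[100] == "T"

    def test_zero_efficiency_rejected_by_domain_check(self):
        with pytest.raises(ValueError):
            EditingSiteSpec(position=10, strand="+", efficiency=0.0)

    def test_half_efficiency_within_binomial_bounds(self, small_plastome):
        site = self._site_on_c(small_plastome, 0.5)
        model = _model(1e-4, tss=[Tss(site.position - 100, "+")],
                       editing_sites=[site])
        tx = ps.simulate_transcripts(small_plastome, model, n=2_000, seed=7)
        covering = [t for t in tx if t.length > 100]
        edited = sum(site.position in t.edited_positions for t in covering)
        lo, hi = stats.binom.interval(0.99, len(covering), 0.5)
        assert lo <= edited <= hi

    def test_site_on_non_c_reference_rejected(self, small_plastome):
        pos = small_plastome.sequence.index("A", 500)
        model = _model(1e-3, editing_sites=[
            EditingSiteSpec(position=pos, strand="+", efficiency=0.5)])
        with pytest.raises(ValueError):
            ps.simulate_transcripts(small_plastome, model, n=5, seed=1)


class TestTranscriptsToReads:
    def test_zero_error_reads_are_genomic_substrings(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        tx = ps.simulate_transcripts(small_plastome, model, n=200, seed=8)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=500, error_rate=0.0, seed=9)
        doubled = small_plastome.sequence * 2
        for r in reads.reads:
            seg = doubled[r.truth.position:r.truth.position + len(r.sequence)]
            expected = seg if r.truth.strand == "+" else ps.revcomp(seg)
            assert r.sequence == expected

    def test_depth_target_within_ten_percent(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        tx = ps.simulate_transcripts(small_plastome, model, n=2_000, seed=10)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        depth_target=50, error_rate=0.0, seed=11)
        observed = sum(len(r.sequence) for r in reads.reads) / small_plastome.length
        assert abs(observed - 50) / 50 < 0.10

    def test_stranded_proportions_follow_antisense_fraction(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000,
                                     antisense_fraction=0.5)
        tx = ps.simulate_transcripts(small_plastome, model, n=2_000, seed=12)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=4_000, error_rate=0.0,
                                        stranded=True, seed=13)
        n_minus = sum(r.truth.strand == "-" for r in reads.reads)
        lo, hi = stats.binom.interval(0.999, len(reads.reads), 0.5)
        assert lo <= n_minus <= hi

    def test_quality_length_matches_sequence(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        tx = ps.simulate_transcripts(small_plastome, model, n=100, seed=14)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=200, error_rate=0.01, seed=15)
        assert all(len(r.quality) == len(r.sequence) for r in reads.reads)

    def test_small_rna_mode_lengths(self, small_plastome):
        model = ps.uniform_tss_model(small_plastome, spacing=2_000)
        tx = ps.simulate_transcripts(small_plastome, model, n=500, seed=16)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=1_000, error_rate=0.0, seed=17,
                                        small_rna=True)
        lengths = {len(r.sequence) for r in reads.reads}
        assert lengths <= set(range(18, 31))

    def test_empty_transcript_pool_rejected(self):
        with pytest.raises(ValueError):
            ps.transcripts_to_reads([], genome_length=1_000, n_reads=10, seed=1)


class TestFullTranscriptionProperty:
    def test_footprints_cover_entire_genome(self, small_plastome):
        # TSS density 1/2kb/strand, mean length 2kb, footprint depth ~20x:
        # the union of transcript footprints covers every position
        model = ps.uniform_tss_model(small_plastome, spacing=2_000,
                                     per_base_termination_prob=5e-4)
        n = 20 * small_plastome.length // 2_000
        tx = ps.simulate_transcripts(small_plastome, model, n=n, seed=18)
        covered = np.zeros(small_plastome.length, dtype=bool)
        L = small_plastome.length
        for t in tx:
            if t.strand == "+":
                idx = (t.start + np.arange(t.length)) % L
            else:
                idx = (t.start - np.arange(t.length)) % L
            covered[idx] = True
        assert covered.all()

    def test_editing_truth_handshake(self, small_plastome):
        # the multiset of edited positions in reads equals the transcripts' truth
        pos = small_plastome.sequence.index("C", 1_000)
        site = EditingSiteSpec(position=pos, strand="+", efficiency=0.7)
        model = _model(5e-4, tss=[Tss(pos - 500, "+")], editing_sites=[site])
        tx = ps.simulate_transcripts(small_plastome, model, n=500, seed=19)
        reads = ps.transcripts_to_reads(tx, genome_length=small_plastome.length,
                                        n_reads=2_000, error_rate=0.0, seed=20)
        doubled = small_plastome.sequence * 2
        for r in reads.reads:
            seg = doubled[r.truth.position:r.truth.position + len(r.sequence)]
            read_fwd = r.sequence if r.truth.strand == "+" else ps.revcomp(r.sequence)
            diffs = [(r.truth.position + i) % small_plastome.length
                     for i, (a, b) in enumerate(zip(read_fwd, seg)) if a != b]
            assert diffs == sorted(r.truth.edited_positions)
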