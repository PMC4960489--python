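"""End-to-end experiment presets: simulate -> trim -> map -> analyze -> report.

A ``RunConfig`` fully determines every output (given the code version): the
master seed is split into named per-stage child seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage,))`` so any stage can be
rerun independently yet reproducibly. Stage logging goes to stderr; results
only to files.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import coverage as cov
from . import editing as ed
from . import io as pio
from . import mapping as mp
from . import nupdna as nd
from . import simulate as sim
from .genome import GenomeSpec, NupInsertion, Plastome, generate_plastome, plant_nupdna

# stage names -> spawn keys, the documented seed derivation
_STAGES = ("genome", "nuclear", "transcripts", "editing", "reads", "subsample", "extra")


def stage_seed(master_seed: int, stage: str) -> int:
    """Child seed for a named stage, derived from the master seed (< 2**31)."""
    key = _STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class NupdnaSettings:
    """nupDNA experiment knobs: what to plant and whether a locus is transcribed."""
    nuclear_length: int = 100_000
    insertions: list[dict] = field(default_factory=lambda: [
        {"source_start": 5_000, "source_end": 6_000, "mode": "snp"},
        {"source_start": 15_000, "source_end": 16_000, "mode": "indel"},
        {"source_start": 25_000, "source_end": 26_200, "mode": "truncated"},
    ])
    transcribe_locus: Optional[int] = None   # index of a planted locus to transcribe
    locus_depth: float = 50.0
    verdict_threshold: float = 0.1


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    seed: int = 1
    outdir: str = "plastoseq_run"
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    tss_spacing: int = 2_000
    per_base_termination_prob: float = 5e-4
    antisense_fraction: Optional[float] = None
    stranded: bool = False
    n_transcripts: int = 3_000
    n_reads: int = 200_000
    read_length: int = 100
    error_rate: float = 0.001
    small_rna: bool = False
    n_editing_sites: int = 0
    editing_efficiency: float = 0.8
    n_snps: int = 0                          # genomic SNPs planted in the sample
    snp_freq: Optional[float] = None         # SNP-call frequency cutoff; None = auto
    max_mismatch: int = 1
    linear: bool = False
    deplete_rrna: bool = False
    subsample_n: Optional[int] = None
    write_artifacts: bool = True
    nupdna: Optional[NupdnaSettings] = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if "genome" in data and isinstance(data["genome"], dict):
            data["genome"] = GenomeSpec(**data["genome"])
        if data.get("nupdna") is not None:
            data["nupdna"] = NupdnaSettings(**data["nupdna"])
        return cls(**data)


def _log(stage: str, t0: float, **counts) -> None:
    msg = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[plastoseq] {stage}: {msg} ({time.time() - t0:.1f}s)", file=sys.stderr)


def _pick_editing_sites(plastome: Plastome, n: int, efficiency: float,
                        seed: int) -> list[sim.EditingSiteSpec]:
    """Choose n genomic C positions (forward strand), evenly spread, as editing sites."""
    del seed  # site choice is deterministic given the genome
    cs = np.frombuffer(plastome.sequence.encode(), dtype=np.uint8) == ord("C")
    positions = np.flatnonzero(cs)
    if positions.size < n:
        raise ValueError("not enough C positions for requested editing sites")
    # circularly even spacing so no two sites (including the first and last,
    # which are circular neighbours) fall within one read length of each other:
    # a read covering two edited sites would exceed the one-mismatch budget
    targets = (np.arange(n) * plastome.length / n).astype(int)
    chosen = sorted({int(positions[np.abs(positions - t).argmin()]) for t in targets})
    if len(chosen) < n:
        raise ValueError("could not place distinct editing sites")
    return [sim.EditingSiteSpec(position=p, strand="+", efficiency=efficiency)
            for p in chosen]


def _simulate_readset(config: RunConfig, plastome: Plastome
                      ) -> tuple[sim.ReadSet, list[sim.Transcript], sim.TranscriptionModel]:
    model = sim.uniform_tss_model(
        plastome, spacing=config.tss_spacing,
        per_base_termination_prob=config.per_base_termination_prob,
        antisense_fraction=config.antisense_fraction,
        editing_sites=_pick_editing_sites(plastome, config.n_editing_sites,
                                          config.editing_efficiency,
                                          stage_seed(config.seed, "editing"))
        if config.n_editing_sites else (),
    )
    transcripts = sim.simulate_transcripts(plastome, model, n=config.n_transcripts,
                                           seed=stage_seed(config.seed, "transcripts"))
    reads = sim.transcripts_to_reads(
        transcripts, genome_length=plastome.length, read_length=config.read_length,
        n_reads=config.n_reads, error_rate=config.error_rate,
        stranded=config.stranded, seed=stage_seed(config.seed, "reads"),
        small_rna=config.small_rna)
    return reads, transcripts, model


def _map_readset(config: RunConfig, plastome: Plastome, reads: sim.ReadSet
                 ) -> tuple[mp.AlignmentSet, sim.ReadSet]:
    trim = mp.quality_trim(reads)
    readset = trim.readset
    if config.subsample_n is not None:
        readset = mp.subsample(readset, config.subsample_n,
                               seed=stage_seed(config.seed, "subsample"))
    index = mp.GenomeIndex(plastome.sequence, circular=not config.linear,
                           name=plastome.name)
    alignments = mp.map_reads(readset, index, max_mismatch=config.max_mismatch)
    if config.deplete_rrna:
        alignments = mp.deplete_rrna(alignments, plastome)
    return alignments, readset


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    from . import __version__
    manifest = {"config": dataclasses.asdict(config), "version": __version__, **extra}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_full_transcription_experiment(config: RunConfig) -> cov.CoverageReport:
    """Whole-plastome transcription preset: the full-coverage analysis chain."""
    t0 = time.time()
    outdir = Path(config.outdir)
    plastome = generate_plastome(config.genome, seed=stage_seed(config.seed, "genome"))
    _log("genome", t0, length=plastome.length, features=len(plastome.features))
    reads, transcripts, model = _simulate_readset(config, plastome)
    _log("simulate", t0, transcripts=len(transcripts), reads=len(reads))
    alignments, kept = _map_readset(config, plastome, reads)
    _log("map", t0, mapped=alignments.n_mapped, multi=alignments.n_discarded_multi,
         unmapped=alignments.n_discarded_unmapped)
    profile = cov.compute_depth(alignments, plastome.length, stranded=config.stranded)
    report = cov.summarize_coverage(profile, plastome, alignments)
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_plastome(outdir / "genome.fasta", outdir / "genome.gff", plastome)
        pio.write_fastq(outdir / "reads.fastq", reads)
        mp.write_alignments_tsv(outdir / "alignments.tsv", alignments)
        pio.write_bedgraph(outdir / "depth.bedgraph", plastome.name, profile.combined())
        if config.stranded:
            pio.write_bedgraph(outdir / "depth_fwd.bedgraph", plastome.name, profile.depth_fwd)
            pio.write_bedgraph(outdir / "depth_rev.bedgraph", plastome.name, profile.depth_rev)
        (outdir / "coverage_report.json").write_text(
            json.dumps(report.to_dict(), indent=1, default=float))
        _write_manifest(outdir, config, {"n_mapped": alignments.n_mapped})
    _log("coverage", t0, covered=f"{report.covered_fraction:.4f}")
    return report


def run_nupdna_experiment(config: RunConfig) -> dict:
    """nupDNA exclusion preset: plant loci, profile diagnostic windows, verdicts."""
    t0 = time.time()
    settings = config.nupdna or NupdnaSettings()
    outdir = Path(config.outdir)
    plastome = generate_plastome(config.genome, seed=stage_seed(config.seed, "genome"))
    insertions = [NupInsertion(**d) for d in settings.insertions]
    nuclear = plant_nupdna(settings.nuclear_length, plastome, insertions,
                           seed=stage_seed(config.seed, "nuclear"))
    _log("plant", t0, loci=len(nuclear.planted_loci))

    reads, transcripts, _ = _simulate_readset(config, plastome)
    if settings.transcribe_locus is not None:
        truth = nuclear.planted_loci[settings.transcribe_locus]
        # the nuclear transcript reads through the insertion edges, so
        # junction-spanning reads exist and flip the junction verdicts too
        extra = _uniform_reads_from(nuclear.sequence,
                                    max(truth.nuclear_start - config.read_length, 0),
                                    min(truth.nuclear_end + config.read_length,
                                        len(nuclear.sequence)),
                                    read_length=config.read_length,
                                    depth=settings.locus_depth,
                                    seed=stage_seed(config.seed, "extra"))
        reads = sim.ReadSet(reads=reads.reads + extra.reads, stranded=reads.stranded)
    _log("simulate", t0, reads=len(reads))

    loci = nd.find_nupdna(nuclear, plastome)
    windows: list[nd.DiagnosticWindow] = []
    for locus in loci:
        windows.extend(nd.build_windows(locus, nuclear, plastome))
    # short planted loci (e.g. truncations below the length filter) still get
    # junction windows from their recorded truth
    profiles = nd.window_depth_profile(windows, reads)
    verdicts = [nd.junction_decline_stat(p, threshold=settings.verdict_threshold)
                for p in profiles]
    _log("nupdna", t0, loci=len(loci), windows=len(windows))

    result = {
        "n_loci": len(loci),
        "windows": [
            {"label": p.window.label, "kind": p.window.site80_kind,
             "depth_at_site80": v.depth_at_site80,
             "flank_median_depth": v.flank_median_depth,
             "plastome_site_depth": v.plastome_site_depth,
             "transcribed_verdict": v.transcribed_verdict}
            for p, v in zip(profiles, verdicts)
        ],
    }
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_plastome(outdir / "genome.fasta", outdir / "genome.gff", plastome)
        pio.write_fasta(outdir / "nuclear.fasta", nuclear.name, nuclear.sequence)
        pio.write_truth_json(outdir / "nupdna_truth.json", nuclear)
        nd.write_loci_bed(outdir / "nupdna_loci.bed", loci)
        nd.write_loci_tsv(outdir / "nupdna_loci.tsv", loci)
        (outdir / "nupdna_verdicts.json").write_text(json.dumps(result, indent=1))
        _write_manifest(outdir, config, {"n_loci": len(loci)})
    return result


def _uniform_reads_from(sequence: str, start: int, end: int, read_length: int,
                        depth: float, seed: int) -> sim.ReadSet:
    """Uniform error-free reads from one interval (a transcribed-locus control)."""
    rng = np.random.default_rng(seed)
    span = end - start
    n = int(round(depth * span / read_length))
    reads = []
    for i in range(n):
        s = start + int(rng.integers(0, max(span - read_length + 1, 1)))
        frag = sequence[s:s + read_length]
        reads.append(sim.Read(id=f"locus{i:06d}", sequence=frag,
                              quality=chr(33 + 40) * len(frag)))
    return sim.ReadSet(reads=reads)


def run_editing_experiment(config: RunConfig) -> dict:
    """RNA-editing preset: plant C-to-U sites, call them back, report recovery."""
    t0 = time.time()
    outdir = Path(config.outdir)
    if config.antisense_fraction is None:
        # editing is a sense-strand event: detection requires the edited strand
        # to dominate coverage at the site, as it does in real plastomes where
        # mRNA far exceeds antisense; symmetric antisense would dilute the
        # edited fraction below the frequency threshold
        config = dataclasses.replace(config, antisense_fraction=0.05)
    plastome = generate_plastome(config.genome, seed=stage_seed(config.seed, "genome"))

    # plant genomic SNPs: the sequenced individual differs from the reference at
    # these positions, so every read carries the alternate base (100% change rate)
    snp_positions: list[int] = []
    sample = plastome
    if config.n_snps > 0:
        seq = list(plastome.sequence)
        cs = np.frombuffer(plastome.sequence.encode(), dtype=np.uint8) == ord("C")
        positions = np.flatnonzero(cs)
        # offset SNPs half a spacing from the editing-site grid so no read
        # covers both a SNP and an edited site (each costs one mismatch)
        targets = ((np.arange(config.n_snps) + 0.5)
                   * plastome.length / max(config.n_editing_sites, config.n_snps)).astype(int)
        for t in targets:
            p = int(positions[np.abs(positions - t).argmin()])
            seq[p] = "T"
            snp_positions.append(p)
        sample = Plastome(sequence="".join(seq), features=plastome.features,
                          name=plastome.name)

    reads, transcripts, model = _simulate_readset(config, sample)
    alignments, kept = _map_readset(config, plastome, reads)
    _log("map", t0, mapped=alignments.n_mapped)
    pileup = ed.build_pileup(alignments, kept, plastome)
    # the printed SNP rule (exactly 100% change rate) is fragile under
    # sequencing error: one errored read at a true SNP drops the frequency
    # below 1.0 and would misclassify it as editing. On error-free data the
    # exact rule applies; on noisy data a 0.95 cutoff tolerates the couple of
    # error reads expected at ~50x while staying far above the frequencies
    # sub-unity editing efficiencies produce.
    snp_freq = config.snp_freq
    if snp_freq is None:
        snp_freq = 1.0 if config.error_rate == 0 else 0.95
    sites = ed.call_sites(pileup, plastome, snp_freq=snp_freq)
    planted = {s.position for s in model.editing_sites}
    called_edited = {s.position for s in sites if s.call == "edited" and s.canonical}
    called_snp = {s.position for s in sites if s.call == "snp"}
    recall = len(planted & called_edited) / len(planted) if planted else None
    fp = sorted(called_edited - planted)
    result = {
        "n_planted": len(planted),
        "n_called_edited": len(called_edited),
        "recall": recall,
        "false_positives": fp,
        "fp_per_10kb": len(fp) / (plastome.length / 10_000),
        "planted_snps": snp_positions,
        "snps_called_snp": sorted(set(snp_positions) & called_snp),
        "snps_called_edited": sorted(set(snp_positions) & called_edited),
        "summary": ed.summarize_calls(sites),
    }
    _log("editing", t0, recall=recall, fp=len(fp))
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
        ed.write_calls_tsv(outdir / "editing_calls.tsv", sites, chrom=plastome.name)
        (outdir / "editing_report.json").write_text(json.dumps(result, indent=1))
        _write_manifest(outdir, config, {"n_called": len(sites)})
    return result
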