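"""Multiple-arrangement transcription simulator.

Models plastome transcription as initiation from many transcription start
sites (TSSs) on both strands combined with inefficient, stochastic
termination: elongation past every base survives with probability
``1 - per_base_termination_prob``, so transcript lengths are geometric-tailed
with mean ~ 1/p. Optional discrete terminator sites add extra stopping
probability when crossed. Precursor transcripts may be C-to-U edited at
chosen sites with sub-100% efficiency, polyadenylated, and are finally
fragmented into error-bearing reads with Phred-style qualities, retaining the
exact ground truth of every read's origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import Plastome, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Tss:
    """A transcription start site with a relative initiation strength."""
    position: int
    strand: str
    relative_strength: float = 1.0


@dataclass(frozen=True)
class TerminatorSite:
    position: int
    strand: str
    efficiency: float  # probability of stopping when crossed, in [0, 1]


@dataclass(frozen=True)
class EditingSiteSpec:
    """A C-to-U editing site: the strand-adjusted reference base must be C."""
    position: int
    strand: str
    efficiency: float  # per-transcript editing probability, in (0, 1]

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("editing efficiency must be in (0, 1]")


@dataclass
class TranscriptionModel:
    """TSS / termination / editing parameterization of plastome transcription."""

    tss_list: list[Tss]
    per_base_termination_prob: float
    terminator_sites: list[TerminatorSite] = field(default_factory=list)
    editing_sites: list[EditingSiteSpec] = field(default_factory=list)
    polyA_tail_length: int = 0
    antisense_fraction: Optional[float] = None  # reweight initiations to the - strand

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError("model must define at least one TSS")
        if not (0.0 < self.per_base_termination_prob <= 1.0):
            raise ValueError("per_base_termination_prob must be in (0, 1]")
        if any(t.relative_strength < 0 for t in self.tss_list):
            raise ValueError("relative_strength must be >= 0")
        if self.antisense_fraction is not None:
            if not (0.0 <= self.antisense_fraction <= 1.0):
                raise ValueError("antisense_fraction must be in [0, 1]")
            if self.antisense_fraction > 0 and not any(t.strand == "-" for t in self.tss_list):
                raise ValueError("antisense_fraction > 0 requires at least one - strand TSS")
            if self.antisense_fraction < 1 and not any(t.strand == "+" for t in self.tss_list):
                raise ValueError("antisense_fraction < 1 requires at least one + strand TSS")

    def validate_editing(self, plastome: Plastome) -> None:
        """Check that each editing site's strand-adjusted reference base is C."""
        for site in self.editing_sites:
            ref = plastome.sequence[site.position]
            ref_on_strand = ref if site.strand == "+" else revcomp(ref)
            if ref_on_strand != "C":
                raise ValueError(
                    f"editing site at {site.position}{site.strand} has reference "
                    f"{ref_on_strand!r}, expected C")

    def tss_weights(self) -> np.ndarray:
        """Initiation sampling weights, optionally rebalanced per strand."""
        w = np.array([t.relative_strength for t in self.tss_list], dtype=float)
        if w.sum() <= 0:
            raise ValueError("total TSS strength must be positive")
        if self.antisense_fraction is not None:
            minus = np.array([t.strand == "-" for t in self.tss_list])
            for mask, target in ((minus, self.antisense_fraction), (~minus, 1 - self.antisense_fraction)):
                s = w[mask].sum()
                if s > 0:
                    w[mask] *= target / s
        return w / w.sum()


def uniform_tss_model(plastome: Plastome, spacing: int = 2_000,
                      per_base_termination_prob: float = 5e-4,
                      both_strands: bool = True,
                      antisense_fraction: Optional[float] = None,
                      editing_sites: Sequence[EditingSiteSpec] = (),
                      ) -> TranscriptionModel:
    """Evenly spaced TSSs at the given density (one per ``spacing`` bp per strand)."""
    tss = [Tss(p, "+") for p in range(0, plastome.length, spacing)]
    if both_strands:
        off = spacing // 2
        tss += [Tss(p, "-") for p in range(off, plastome.length, spacing)]
    return TranscriptionModel(tss_list=tss,
                              per_base_termination_prob=per_base_termination_prob,
                              editing_sites=list(editing_sites),
                              antisense_fraction=antisense_fraction)


@dataclass
class Transcript:
    """A precursor transcript; ``sequence`` is in transcript orientation.

    The footprint runs from ``start`` in the strand direction for ``length``
    bases, wrapping circularly; the polyA tail (if any) is appended to
    ``sequence`` but is not part of the genomic footprint.
    """

    id: str
    start: int
    strand: str
    length: int
    sequence: str
    edited_positions: list[int] = field(default_factory=list)

    def genomic_position(self, offset: int, genome_length: int) -> int:
        """Genomic coordinate of transcript offset (transcript orientation)."""
        if self.strand == "+":
            return (self.start + offset) % genome_length
        return (self.start - offset) % genome_length

    def offset_of(self, position: int, genome_length: int) -> int:
        """Transcript offset of a genomic position (may exceed length)."""
        if self.strand == "+":
            return (position - self.start) % genome_length
        return (self.start - position) % genome_length


def _transcript_sequence(plastome: Plastome, start: int, strand: str, length: int) -> str:
    L = plastome.length
    if strand == "+":
        end = start + length
        if end <= L:
            seq = plastome.sequence[start:end]
        else:
            seq = plastome.sequence[start:] + plastome.sequence[:end - L]
        return seq
    # minus strand: forward-coordinate footprint is [start-length+1, start]
    lo = (start - length + 1) % L
    if lo + length <= L:
        fwd = plastome.sequence[lo:lo + length]
    else:
        fwd = plastome.sequence[lo:] + plastome.sequence[:(lo + length) % L]
    return revcomp(fwd)


def simulate_transcripts(plastome: Plastome, model: TranscriptionModel, n: int,
                         seed: int, max_length: Optional[int] = None) -> list[Transcript]:
    """Sample ``n`` precursor transcripts from the model.

    Each transcript starts at a TSS drawn by relative strength and elongates
    until per-base stochastic termination fires (geometric lengths, mean 1/p),
    a terminator site stops it, or the length cap (default: one full genome
    lap) is reached.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate_editing(plastome)
    rng = np.random.default_rng(seed)
    L = plastome.length
    cap = max_length if max_length is not None else L
    p = model.per_base_termination_prob

    weights = model.tss_weights()
    tss_idx = rng.choice(len(model.tss_list), size=n, p=weights)

    if model.terminator_sites:
        term_by_strand = {
            "+": sorted((t.position, t.efficiency) for t in model.terminator_sites if t.strand == "+"),
            "-": sorted((t.position, t.efficiency) for t in model.terminator_sites if t.strand == "-"),
        }
        lengths = np.empty(n, dtype=np.int64)
        for i, ti in enumerate(tss_idx):
            tss = model.tss_list[int(ti)]
            length = 0
            pos = tss.position
            while length < cap:
                g = int(rng.geometric(p)) if p < 1.0 else 1
                nxt_len, eff = _next_terminator(term_by_strand[tss.strand], pos, length, cap, L, tss.strand)
                if nxt_len is None or length + g < nxt_len:
                    length = min(length + g, cap)
                    break
                length = nxt_len
                pos = tss.position + (length - 1) if tss.strand == "+" else tss.position - (length - 1)
                if rng.random() < eff:
                    break
            lengths[i] = length
    else:
        lengths = np.minimum(rng.geometric(p, size=n) if p < 1.0 else np.ones(n, dtype=np.int64), cap)

    tail = "A" * model.polyA_tail_length
    transcripts = []
    for i, (ti, length) in enumerate(zip(tss_idx, lengths)):
        tss = model.tss_list[int(ti)]
        seq = _transcript_sequence(plastome, tss.position, tss.strand, int(length))
        transcripts.append(Transcript(id=f"tx{i:06d}", start=tss.position, strand=tss.strand,
                                      length=int(length), sequence=seq + tail))
    if model.editing_sites:
        apply_editing(transcripts, model.editing_sites, int(rng.integers(2**31)),
                      genome_length=L)
    return transcripts


def _next_terminator(terms, pos, length, cap, L, strand):
    """Length at which the next terminator (same strand) would be reached."""
    best = None
    for tpos, eff in terms:
        d = (tpos - pos) % L if strand == "+" else (pos - tpos) % L
        if d == 0:
            continue
        cand = length + d
        if cand <= cap and (best is None or cand < best[0]):
            best = (cand, eff)
    return best if best else (None, None)


def apply_editing(transcripts: list[Transcript], editing_sites: Sequence[EditingSiteSpec],
                  seed: int, genome_length: Optional[int] = None) -> list[Transcript]:
    """Apply C-to-U editing to each covered site independently per transcript.

    The edited base is represented as T in the transcript sequence (cDNA
    convention). Sites act only on transcripts of their own strand. Mutates
    and returns the input list.
    """
    rng = np.random.default_rng(seed)
    for t in transcripts:
        L = genome_length if genome_length is not None else max(t.length, t.start + 1)
        seq = None
        for site in editing_sites:
            if site.strand != t.strand:
                continue
            off = t.offset_of(site.position, L)
            if off >= t.length:
                continue
            if t.sequence[off] not in ("C", "T"):
                raise ValueError(
                    f"editing site {site.position}{site.strand}: transcript base "
                    f"{t.sequence[off]!r} is not C")
            if rng.random() < site.efficiency:
                if seq is None:
                    seq = list(t.sequence)
                seq[off] = "T"
                t.edited_positions.append(site.position)
        if seq is not None:
            t.sequence = "".join(seq)
    return transcripts


@dataclass
class ReadTruth:
    """Simulation ground truth for one read: where it must map."""
    position: int        # forward-coordinate start of the expected placement
    strand: str          # expected alignment strand
    transcript_id: str
    edited_positions: tuple[int, ...] = ()


@dataclass
class Read:
    id: str
    sequence: str
    quality: str
    truth: Optional[ReadTruth] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("quality string length must equal sequence length")


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    stranded: bool = False

    def __len__(self) -> int:
        return len(self.reads)


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    return chr(33 + q)


def transcripts_to_reads(transcripts: Sequence[Transcript], genome_length: int,
                         read_length: int = 100,
                         n_reads: Optional[int] = None,
                         depth_target: Optional[float] = None,
                         error_rate: float = 0.001,
                         stranded: bool = False,
                         min_emit_length: int = 30,
                         seed: int = 0,
                         small_rna: bool = False) -> ReadSet:
    """Fragment transcripts into sequencing reads with per-base errors.

    Fragments start uniformly along each transcript; transcripts are drawn
    with probability proportional to their number of valid fragment starts so
    coverage tracks transcript footprint. ``depth_target`` sets the read count
    as ``depth * genome_length / read_length`` unless ``n_reads`` is given.
    In ``small_rna`` mode each read's length is drawn uniformly from
    [18, 30] bp, emulating small-RNA libraries.

    Unstranded mode flips each read to the opposite orientation with
    probability 1/2; stranded mode preserves the transcript strand. Truth
    records the expected unique placement (forward-coordinate start, strand)
    and the edited sites the fragment covers.
    """
    if not transcripts:
        raise ValueError("empty transcript pool")
    if small_rna:
        min_emit_length = 18
    if read_length < min_emit_length:
        raise ValueError("read_length must be >= min_emit_length")
    if n_reads is None:
        if depth_target is None:
            raise ValueError("provide n_reads or depth_target")
        n_reads = int(round(depth_target * genome_length / read_length))

    rng = np.random.default_rng(seed)
    lengths = np.array([t.length for t in transcripts], dtype=np.int64)
    starts_per_tx = np.where(lengths >= read_length, lengths - read_length + 1,
                             (lengths >= min_emit_length).astype(np.int64))
    if starts_per_tx.sum() == 0:
        raise ValueError("no transcript is long enough to emit a read")
    probs = starts_per_tx / starts_per_tx.sum()
    tx_idx = rng.choice(len(transcripts), size=n_reads, p=probs)
    offsets = np.floor(rng.random(n_reads) * starts_per_tx[tx_idx]).astype(np.int64)
    if small_rna:
        rlens = rng.integers(18, 31, size=n_reads)
    else:
        rlens = np.full(n_reads, read_length, dtype=np.int64)
    flips = rng.random(n_reads) < 0.5 if not stranded else np.zeros(n_reads, dtype=bool)
    n_errors = rng.binomial(rlens, error_rate) if error_rate > 0 else np.zeros(n_reads, dtype=np.int64)
    qchar = _phred_char(error_rate)

    reads: list[Read] = []
    L = genome_length
    for i in range(n_reads):
        t = transcripts[int(tx_idx[i])]
        off = int(offsets[i])
        flen = min(int(rlens[i]), t.length - off, len(t.sequence) - off)
        if flen < min_emit_length:
            flen = min(t.length, int(rlens[i]))
            off = 0
        frag = t.sequence[off:off + flen]
        if n_errors[i] > 0:
            pos = rng.choice(flen, size=min(int(n_errors[i]), flen), replace=False)
            frag_l = list(frag)
            for p in pos:
                frag_l[p] = "ACGT"[(_BASE_INDEX.get(frag_l[p], 0) + int(rng.integers(1, 4))) % 4]
            frag = "".join(frag_l)
        # expected placement: leftmost forward coordinate of the fragment footprint
        if t.strand == "+":
            gstart = (t.start + off) % L
        else:
            gstart = (t.start - off - flen + 1) % L
        strand = t.strand
        seq = frag
        if flips[i]:
            seq = revcomp(frag)
            strand = "-" if strand == "+" else "+"
        covered = tuple(p for p in t.edited_positions
                        if t.offset_of(p, L) >= off and t.offset_of(p, L) < off + flen)
        reads.append(Read(
            id=f"read{i:07d}",
            sequence=seq,
            quality=qchar * flen,
            truth=ReadTruth(position=gstart, strand=strand, transcript_id=t.id,
                            edited_positions=covered),
        ))
    return ReadSet(reads=reads, stranded=stranded)
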