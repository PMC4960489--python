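"""Unique-placement read mapping with a one-mismatch budget.

Implements the stringent alignment policy used throughout the analysis:
reads are 3'-quality-trimmed, then placed on the (circularized) genome with
ungapped alignment allowing at most ``max_mismatch`` substitutions; a read is
kept only when exactly one placement achieves the minimum mismatch count
(best-stratum uniqueness), otherwise it is discarded as multi-mapping.
Mismatches are plain Hamming counts, not quality-weighted.

The mapper is hash-seeded: by the pigeonhole principle a read with at most
one mismatch has at least one of two disjoint k-mer seeds matching exactly,
so candidate positions come from two dictionary lookups and are then verified
by direct comparison. Zero-mismatch mode (used by the nupDNA diagnostic)
needs only a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome import FeatureClass, Plastome, revcomp
from .simulate import Read, ReadSet


@dataclass(frozen=True)
class Alignment:
    """A unique placement of one read; ``position`` is 0-based, mod genome length."""
    read_id: str
    position: int
    strand: str
    n_mismatch: int
    length: int
    unique: bool = True


@dataclass
class AlignmentSet:
    alignments: list[Alignment] = field(default_factory=list)
    n_input_reads: int = 0
    n_mapped: int = 0
    n_discarded_multi: int = 0
    n_discarded_unmapped: int = 0
    n_rrna_removed: int = 0
    reference_length: int = 0
    stranded: bool = False

    def __post_init__(self) -> None:
        total = self.n_mapped + self.n_discarded_multi + self.n_discarded_unmapped
        if self.n_input_reads and total != self.n_input_reads:
            raise ValueError("alignment counts do not sum to input reads")


@dataclass
class TrimResult:
    readset: ReadSet
    n_input: int
    n_kept: int
    n_dropped_short: int
    n_bases_trimmed: int


def quality_trim(reads: ReadSet, min_phred: int = 20, min_length: int = 30) -> TrimResult:
    """3'-trim low-quality bases and drop short reads.

    Trailing bases with Phred quality <= ``min_phred`` are removed (the kept
    prefix is the longest one whose final base passes); reads whose trimmed
    length is not strictly greater than ``min_length`` are dropped.
    """
    cutoff = chr(33 + min_phred)
    kept: list[Read] = []
    n_trimmed = 0
    for r in reads.reads:
        q = r.quality
        if len(q) != len(r.sequence):
            raise ValueError(f"malformed quality string for read {r.id}")
        i = len(q)
        while i > 0 and q[i - 1] <= cutoff:
            i -= 1
        n_trimmed += len(q) - i
        if i > min_length:
            if i == len(q):
                kept.append(r)
            else:
                kept.append(replace(r, sequence=r.sequence[:i], quality=q[:i]))
    return TrimResult(readset=ReadSet(reads=kept, stranded=reads.stranded),
                      n_input=len(reads.reads), n_kept=len(kept),
                      n_dropped_short=len(reads.reads) - len(kept),
                      n_bases_trimmed=n_trimmed)


class GenomeIndex:
    """Exact k-mer position index over a (possibly circular) reference.

    For a circular reference the first ``max_read_length - 1`` bases are
    appended so wrap-around placements exist in the extended string; reported
    positions are always in [0, L). ``--linear`` behaviour (no wrap) is
    obtained with ``circular=False``.
    """

    SEED_LONG = 15   # reads >= 30 bp
    SEED_SHORT = 9   # small-RNA reads >= 18 bp

    def __init__(self, sequence: str, circular: bool = True, max_read_length: int = 151,
                 name: str = "ref"):
        self.length = len(sequence)
        self.circular = circular
        self.name = name
        pad = max_read_length - 1 if circular else 0
        self.ext = sequence + sequence[:pad]
        self._tables: dict[int, dict[str, list[int]]] = {}

    def table(self, k: int) -> dict[str, list[int]]:
        if k not in self._tables:
            table: dict[str, list[int]] = {}
            ext = self.ext
            n = self.length if self.circular else max(self.length - k + 1, 0)
            for p in range(n):
                table.setdefault(ext[p:p + k], []).append(p)
            self._tables[k] = table
        return self._tables[k]

    def seed_length(self, read_length: int, max_mismatch: int) -> int:
        n_seeds = max_mismatch + 1
        for k in (self.SEED_LONG, self.SEED_SHORT):
            if read_length >= n_seeds * k:
                return k
        raise ValueError(f"read of length {read_length} shorter than index seed length")


def _candidates(index: GenomeIndex, seq: str, k: int, n_seeds: int) -> set[int]:
    table = index.table(k)
    cands: set[int] = set()
    for s in range(n_seeds):
        off = s * k
        for p in table.get(seq[off:off + k], ()):
            c = p - off
            if index.circular:
                cands.add(c % index.length)
            elif 0 <= c <= index.length - len(seq):
                cands.add(c)
    return cands


def _mismatches(ext: str, pos: int, seq: str, budget: int) -> int:
    seg = ext[pos:pos + len(seq)]
    if seg == seq:
        return 0
    n = 0
    for a, b in zip(seq, seg):
        if a != b:
            n += 1
            if n > budget:
                return n
    return n


def _map_one(seq: str, index: GenomeIndex, max_mismatch: int) -> tuple[Optional[Alignment], str]:
    """Map one sequence; returns (alignment-or-None, status in {mapped, multi, unmapped})."""
    k = index.seed_length(len(seq), max_mismatch)
    n_seeds = max_mismatch + 1
    best = max_mismatch + 1
    hits: list[tuple[int, str]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for cand in _candidates(index, s, k, n_seeds):
            m = _mismatches(index.ext, cand, s, max_mismatch)
            if m > max_mismatch:
                continue
            if m < best:
                best = m
                hits = [(cand, strand)]
            elif m == best:
                hits.append((cand, strand))
    if not hits:
        return None, "unmapped"
    hits = list(dict.fromkeys(hits))
    if len(hits) > 1:
        return None, "multi"
    pos, strand = hits[0]
    return Alignment(read_id="", position=pos, strand=strand, n_mismatch=best,
                     length=len(seq)), "mapped"


def map_read(read: Read, index: GenomeIndex, max_mismatch: int = 1) -> Optional[Alignment]:
    """Map a single read; None when unmapped or multi-placed at the best stratum."""
    aln, status = _map_one(read.sequence, index, max_mismatch)
    if aln is None:
        return None
    return replace(aln, read_id=read.id)


def map_reads(reads: ReadSet, index: GenomeIndex, max_mismatch: int = 1) -> AlignmentSet:
    """Map a read set under the unique-placement policy, with discard accounting."""
    alignments: list[Alignment] = []
    n_multi = n_unmapped = 0
    for r in reads.reads:
        aln, status = _map_one(r.sequence, index, max_mismatch)
        if status == "mapped":
            alignments.append(replace(aln, read_id=r.id))
        elif status == "multi":
            n_multi += 1
        else:
            n_unmapped += 1
    return AlignmentSet(alignments=alignments, n_input_reads=len(reads.reads),
                        n_mapped=len(alignments), n_discarded_multi=n_multi,
                        n_discarded_unmapped=n_unmapped,
                        reference_length=index.length, stranded=reads.stranded)


def deplete_rrna(alignments: AlignmentSet, plastome: Plastome) -> AlignmentSet:
    """Remove alignments overlapping any annotated rRNA gene by >= 1 bp."""
    rrna = np.zeros(plastome.length, dtype=np.int64)
    for f in plastome.features_of_class(FeatureClass.RRNA):
        rrna[f.start:f.end] = 1
    if rrna.sum() == 0:
        return alignments
    csum = np.concatenate([[0], np.cumsum(rrna)])
    L = plastome.length
    kept: list[Alignment] = []
    removed = 0
    for a in alignments.alignments:
        s, e = a.position, a.position + a.length
        if e <= L:
            overlap = csum[e] - csum[s]
        else:
            overlap = (csum[L] - csum[s]) + csum[e - L]
        if overlap > 0:
            removed += 1
        else:
            kept.append(a)
    return AlignmentSet(alignments=kept, n_input_reads=alignments.n_input_reads,
                        n_mapped=len(kept),
                        n_discarded_multi=alignments.n_discarded_multi,
                        n_discarded_unmapped=alignments.n_discarded_unmapped + removed,
                        n_rrna_removed=removed,
                        reference_length=alignments.reference_length,
                        stranded=alignments.stranded)


def subsample(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement, deterministic under seed."""
    if n > len(reads.reads):
        raise ValueError(f"cannot subsample {n} from {len(reads.reads)} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads.reads), size=n, replace=False))
    return ReadSet(reads=[reads.reads[int(i)] for i in idx], stranded=reads.stranded)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sam(path, alignments: AlignmentSet, reads: ReadSet, reference_name: str = "plastome") -> None:
    """Write alignments as minimal SAM (header + 11 mandatory columns + NM).

    Wrap-around placements on a circular reference are written at their start
    position with a full-length match CIGAR; consumers that require linear
    coordinates should map with ``circular=False``.
    """
    by_id = {r.id: r for r in reads.reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{alignments.reference_length}\n")
        fh.write("@PG\tID:plastoseq\tPN:plastoseq\n")
        for a in alignments.alignments:
            r = by_id[a.read_id]
            flag = 16 if a.strand == "-" else 0
            seq = revcomp(r.sequence) if a.strand == "-" else r.sequence
            qual = r.quality[::-1] if a.strand == "-" else r.quality
            fh.write("\t".join([
                a.read_id, str(flag), reference_name, str(a.position + 1), "255",
                f"{a.length}M", "*", "0", "0", seq, qual, f"NM:i:{a.n_mismatch}",
            ]) + "\n")


def write_alignments_tsv(path, alignments: AlignmentSet) -> None:
    import pandas as pd
    df = pd.DataFrame([{
        "read_id": a.read_id, "position": a.position, "strand": a.strand,
        "n_mismatch": a.n_mismatch, "length": a.length,
    } for a in alignments.alignments])
    df.to_csv(path, sep="\t", index=False)
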