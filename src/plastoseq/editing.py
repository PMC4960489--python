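"""C-to-U RNA-editing site calling from read pileups.

Plastid transcripts undergo C-to-U editing: specific genomic cytosines appear
as T in cDNA reads. A site is called edited when read depth >= 10, at least
5 reads carry the alternate base, and the alternate frequency is >= 0.5 but
below 100%; positions where the change rate is exactly 100% are genomic SNPs,
not editing. Both thresholds (count and frequency) apply conjunctively --
at high depth they can disagree, and the frequency rule then dominates.

Counts are strand-adjusted: a read placed on the minus strand supports C-to-U
at a minus-strand C through its reverse complement, which in forward genomic
space reads as G-to-A. The default (unstranded) caller therefore works in
forward genomic space and flags both C>T and G>A as canonical C-to-U events
(on the + and - strand respectively); all other transitions are reported with
their own class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import Plastome, revcomp
from .mapping import AlignmentSet
from .simulate import Read, ReadSet

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i

#: canonical C-to-U signatures in forward genomic space: (ref, alt) -> strand
CANONICAL = {("C", "T"): "+", ("G", "A"): "-"}


@dataclass
class Pileup:
    """Per-position base counts by alignment strand, in forward genomic space.

    ``counts`` has shape (2 strands [+,-], 4 bases [A,C,G,T], genome length).
    Minus-strand reads are complemented into forward space before counting, so
    ``combined()`` is directly comparable to the forward reference.
    """

    counts: np.ndarray
    length: int

    def combined(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def depth(self) -> np.ndarray:
        return self.combined().sum(axis=0)


def build_pileup(alignments: AlignmentSet, reads: ReadSet | Sequence[Read],
                 plastome: Plastome) -> Pileup:
    """Tally aligned read bases at every covered position (wrap-aware).

    Base counts conserve read bases: the total count equals the summed length
    of the mapped reads.
    """
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    by_id = {r.id: r for r in read_list}
    L = plastome.length
    counts = np.zeros((2, 4, L), dtype=np.int64)
    chunks: dict[int, list[np.ndarray]] = {0: [], 1: []}
    poss: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for a in alignments.alignments:
        r = by_id[a.read_id]
        if len(r.sequence) != a.length:
            raise ValueError(f"alignment/read length mismatch for {a.read_id}")
        seq = r.sequence if a.strand == "+" else revcomp(r.sequence)
        codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        pos = (a.position + np.arange(a.length)) % L
        sidx = 0 if a.strand == "+" else 1
        chunks[sidx].append(codes)
        poss[sidx].append(pos)
    for sidx in (0, 1):
        if not chunks[sidx]:
            continue
        codes = np.concatenate(chunks[sidx])
        pos = np.concatenate(poss[sidx])
        valid = codes >= 0
        flat = codes[valid].astype(np.int64) * L + pos[valid]
        counts[sidx] += np.bincount(flat, minlength=4 * L).reshape(4, L)
    return Pileup(counts=counts, length=L)


@dataclass(frozen=True)
class EditingSite:
    """One called site; ``frequency`` is alt_count / depth at the position."""

    position: int
    strand: str
    ref_base: str           # forward genomic space
    alt_base: str
    depth: int
    alt_count: int
    frequency: float
    call: str               # "edited" | "snp"
    transition_class: str   # e.g. "C>T"
    canonical: bool         # True for C-to-U (C>T fwd / G>A rev)


def call_sites(pileup: Pileup, plastome: Plastome,
               min_depth: int = 10, min_alt: int = 5, min_freq: float = 0.5,
               snp_freq: float = 1.0) -> list[EditingSite]:
    """Call editing sites and SNPs from a pileup.

    A site passes when depth >= ``min_depth``, alternate count >= ``min_alt``
    and frequency >= ``min_freq``; it is classified ``snp`` when the frequency
    reaches ``snp_freq`` (exactly 1.0 by default -- for noisy data a slightly
    lower cutoff such as 0.99 can be supplied), otherwise ``edited``. All
    transitions are reported; C-to-U events (C>T forward, G>A reverse) carry
    ``canonical=True``. Deterministic: identical pileups give identical calls.
    """
    combined = pileup.combined()
    depth = combined.sum(axis=0)
    ref_codes = _BASE_CODE[np.frombuffer(plastome.sequence.encode(), dtype=np.uint8)]
    sites: list[EditingSite] = []
    candidate = np.flatnonzero(depth >= min_depth)
    for pos in candidate:
        ref_i = int(ref_codes[pos])
        if ref_i < 0:
            continue
        d = int(depth[pos])
        for alt_i in range(4):
            if alt_i == ref_i:
                continue
            alt = int(combined[alt_i, pos])
            if alt < min_alt:
                continue
            freq = alt / d
            if freq < min_freq:
                continue
            ref_b, alt_b = _BASES[ref_i], _BASES[alt_i]
            strand = CANONICAL.get((ref_b, alt_b), "+")
            sites.append(EditingSite(
                position=int(pos), strand=strand, ref_base=ref_b, alt_base=alt_b,
                depth=d, alt_count=alt, frequency=freq,
                call="snp" if freq >= snp_freq else "edited",
                transition_class=f"{ref_b}>{alt_b}",
                canonical=(ref_b, alt_b) in CANONICAL))
    return sites


def summarize_calls(sites: Sequence[EditingSite]) -> dict:
    """Counts per call and transition class."""
    out = {"n_edited": 0, "n_snp": 0, "n_canonical_edited": 0, "by_class": {}}
    for s in sites:
        key = s.transition_class
        out["by_class"][key] = out["by_class"].get(key, 0) + 1
        if s.call == "edited":
            out["n_edited"] += 1
            if s.canonical:
                out["n_canonical_edited"] += 1
        else:
            out["n_snp"] += 1
    return out


def write_calls_tsv(path, sites: Sequence[EditingSite], chrom: str = "plastome") -> None:
    """VCF-like TSV: CHROM, POS (1-based), REF, ALT, DP, AD, FREQ, CLASS, CALL."""
    import pandas as pd
    pd.DataFrame([{
        "CHROM": chrom, "POS": s.position + 1, "REF": s.ref_base, "ALT": s.alt_base,
        "DP": s.depth, "AD": s.alt_count, "FREQ": round(s.frequency, 4),
        "CLASS": s.transition_class, "CALL": s.call,
    } for s in sites]).to_csv(path, sep="\t", index=False)
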