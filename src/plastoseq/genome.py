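"""Synthetic plastome and nuclear-genome generation.

The plastid genome (plastome) of green plants is a circular DNA of roughly
100-200 kb carrying protein-coding genes, tRNAs, rRNAs, introns, and, in some
algae, substantial internal repeats plus a large inverted-repeat (IR) pair.
This module builds reduced but structurally faithful plastomes with a
controlled feature composition, and nuclear sequences carrying plastome-derived
insertions (nupDNAs) with recorded divergence, so that every downstream
analysis (coverage, editing, nupDNA exclusion) can be validated against an
exact planted truth.

Coordinates are 0-based half-open throughout; GFF3 I/O converts to 1-based
inclusive at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: per-position classification labels, in precedence order
CODING = "coding"
INTRON = "intron"
INTERGENIC = "intergenic"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureClass(str, Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    INTRON = "intron"
    REPEAT = "repeat"
    INVERTED_REPEAT = "inverted_repeat"


#: feature classes whose positions count as coding
CODING_CLASSES = frozenset({FeatureClass.CDS, FeatureClass.TRNA, FeatureClass.RRNA})


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the genome.

    ``start``/``end`` are 0-based half-open; wrapping features are stored split
    into two non-wrapping intervals, so ``start < end`` always holds.
    ``masked`` marks features whose positions belong to the repeat mask
    (dispersed repeat copies, the second IR copy).
    """

    feature_class: FeatureClass
    start: int
    end: int
    strand: str = "+"
    id: str = ""
    masked: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Plastome:
    """A circular plastid genome: sequence, typed features, repeat mask."""

    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True
    name: str = "plastome"

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.id!r} exceeds genome length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def repeat_mask(self) -> set[int]:
        """Positions belonging to masked repeat elements."""
        mask: set[int] = set()
        for f in self.features:
            if f.masked:
                mask.update(range(f.start, f.end))
        return mask

    def repeat_mask_array(self) -> np.ndarray:
        """Boolean array of masked positions (len == genome length)."""
        arr = np.zeros(self.length, dtype=bool)
        for f in self.features:
            if f.masked:
                arr[f.start:f.end] = True
        return arr

    def features_of_class(self, cls: FeatureClass) -> list[Feature]:
        return [f for f in self.features if f.feature_class is cls]


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic plastome.

    ``repeat_unit_length`` defaults to 2 kb so that identical repeat copies
    are much longer than a read and genuinely defeat unique placement.
    """

    length: int = 50_000
    n_genes: int = 30
    mean_gene_length: int = 900
    intron_rate: float = 0.2
    n_trna: int = 4
    n_rrna: int = 2
    repeat_fraction: float = 0.0
    repeat_unit_length: int = 2_000
    ir_length: int = 0

    def __post_init__(self) -> None:
        if self.length < 5_000:
            raise ValueError("genome length must be >= 5000")
        if not (0.0 <= self.repeat_fraction <= 0.5):
            raise ValueError("repeat_fraction must be in [0, 0.5]")


class _FreeSpace:
    """Greedy allocator of disjoint intervals inside [0, L)."""

    def __init__(self, length: int, rng: np.random.Generator, pad: int = 20):
        self.free: list[tuple[int, int]] = [(0, length)]
        self.rng = rng
        self.pad = pad

    def reserve(self, size: int) -> int:
        # best-fit-decreasing: use the largest gap to limit fragmentation
        need = size + 2 * self.pad
        if not self.free:
            raise ValueError("requested features cannot fit in the genome")
        i = max(range(len(self.free)), key=lambda j: self.free[j][1] - self.free[j][0])
        s, e = self.free[i]
        if e - s < need:
            raise ValueError("requested features cannot fit in the genome")
        off = int(self.rng.integers(s + self.pad, e - self.pad - size + 1))
        self.free[i:i + 1] = [iv for iv in ((s, off), (off + size, e)) if iv[1] - iv[0] > 0]
        return off


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def generate_plastome(config: GenomeSpec, seed: int) -> Plastome:
    """Generate a reproducible synthetic plastome.

    The layout is built deterministically from ``(config, seed)``: dispersed
    identical repeat copies (if ``repeat_fraction > 0``) and the IR pair are
    reserved first, then genes (CDS/tRNA/rRNA, a fraction of CDS with a single
    internal intron) are placed in the remaining intergenic space.

    Raises ``ValueError`` when the requested features cannot fit.
    """
    rng = np.random.default_rng(seed)
    L = config.length
    seq = np.frombuffer(_random_sequence(rng, L).encode(), dtype=np.uint8).copy()
    alloc = _FreeSpace(L, rng)
    features: list[Feature] = []

    # budget check before any placement
    n_rep = math.ceil(config.repeat_fraction * L / config.repeat_unit_length) if config.repeat_fraction > 0 else 0
    total = (n_rep * config.repeat_unit_length + 2 * config.ir_length
             + config.n_genes * config.mean_gene_length
             + config.n_trna * 80 + config.n_rrna * 1500)
    if total > 0.9 * L:
        raise ValueError("total feature length exceeds genome capacity")

    # inverted repeat: one source copy and one explicit reverse-complement copy
    if config.ir_length > 0:
        a = alloc.reserve(config.ir_length)
        b = alloc.reserve(config.ir_length)
        ir_seq = seq[a:a + config.ir_length].tobytes().decode()
        seq[b:b + config.ir_length] = np.frombuffer(revcomp(ir_seq).encode(), dtype=np.uint8)
        features.append(Feature(FeatureClass.INVERTED_REPEAT, a, a + config.ir_length, "+", "IR-A"))
        features.append(Feature(FeatureClass.INVERTED_REPEAT, b, b + config.ir_length, "-", "IR-B", masked=True))

    # dispersed identical repeat copies
    if n_rep > 0:
        unit = _random_sequence(rng, config.repeat_unit_length)
        unit_arr = np.frombuffer(unit.encode(), dtype=np.uint8)
        for i in range(n_rep):
            s = alloc.reserve(config.repeat_unit_length)
            seq[s:s + config.repeat_unit_length] = unit_arr
            features.append(Feature(FeatureClass.REPEAT, s, s + config.repeat_unit_length,
                                    "+", f"repeat{i + 1:03d}", masked=True))

    # genes: rRNA, tRNA, then protein-coding (some with one internal intron)
    def place_gene(size: int, cls: FeatureClass, gid: str, with_intron: bool) -> None:
        s = alloc.reserve(size)
        strand = "+" if rng.random() < 0.5 else "-"
        if with_intron and size >= 300:
            exon1 = size // 3
            intron = size // 3
            features.append(Feature(cls, s, s + exon1, strand, f"{gid}.e1"))
            features.append(Feature(FeatureClass.INTRON, s + exon1, s + exon1 + intron, strand, f"{gid}.i1"))
            features.append(Feature(cls, s + exon1 + intron, s + size, strand, f"{gid}.e2"))
        else:
            features.append(Feature(cls, s, s + size, strand, gid))

    for i in range(config.n_rrna):
        place_gene(int(rng.integers(1200, 1800)), FeatureClass.RRNA, f"rrn{i + 1}", False)
    for i in range(config.n_trna):
        place_gene(int(rng.integers(70, 90)), FeatureClass.TRNA, f"trn{i + 1}", False)
    sizes = np.clip(rng.normal(config.mean_gene_length, config.mean_gene_length / 4,
                               size=config.n_genes), 200, 3000).astype(int)
    introns = rng.random(config.n_genes) < config.intron_rate
    for i in np.argsort(sizes)[::-1]:       # largest first, against fragmentation
        place_gene(int(sizes[i]), FeatureClass.CDS, f"gene{i + 1:04d}", bool(introns[i]))

    features.sort(key=lambda f: (f.start, f.end))
    return Plastome(sequence=seq.tobytes().decode("ascii"), features=features)


def classify_positions(plastome: Plastome) -> np.ndarray:
    """Classify every position as coding / intron / intergenic.

    Coding regions are protein-coding, rRNA and tRNA genes; non-coding regions
    are introns and intergenic space. When annotations overlap, precedence is
    coding > intron > intergenic (a position inside an annotated exon is
    coding even if an intron annotation also covers it).
    """
    vec = np.full(plastome.length, INTERGENIC, dtype="U10")
    for f in plastome.features:
        if f.feature_class is FeatureClass.INTRON:
            vec[f.start:f.end] = INTRON
    for f in plastome.features:
        if f.feature_class in CODING_CLASSES:
            vec[f.start:f.end] = CODING
    return vec


# ---------------------------------------------------------------------------
# nupDNA planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NupInsertion:
    """Request to plant one plastome-derived insertion.

    ``mode`` controls the discriminating difference: ``exact`` (optionally
    diverged to ``identity`` by scattered substitutions), ``snp``/``indel``
    (exactly one difference at the interval midpoint), or ``truncated`` (only
    the first half of the source is inserted, so the insertion's right edge is
    a junction with nuclear background).
    """

    source_start: int
    source_end: int
    mode: str = "exact"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.source_end - self.source_start < 160:
            raise ValueError("source interval must be >= 160 bp")
        if not (0.80 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0.80, 1.0]")
        if self.mode not in ("exact", "snp", "indel", "truncated"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class NupDnaTruth:
    """Ground truth for one planted nupDNA locus.

    ``edit_ops`` is the exact sequence of operations applied to the plastome
    source interval, each as a JSON-friendly tuple:
    ``("sub", offset, new_base)``, ``("del", offset)``, ``("trunc", keep_len)``.
    Re-applying them to the source must reproduce the planted sequence.
    """

    nuclear_start: int
    nuclear_end: int
    source_start: int
    source_end: int
    mode: str
    identity: float
    variant_offset: int | None
    edit_ops: tuple = ()

    def reconstruct(self, plastome: Plastome) -> str:
        seq = list(plastome.sequence[self.source_start:self.source_end])
        for op in self.edit_ops:
            if op[0] == "sub":
                seq[op[1]] = op[2]
            elif op[0] == "del":
                del seq[op[1]]
            elif op[0] == "trunc":
                seq = seq[:op[1]]
            else:  # pragma: no cover
                raise ValueError(f"unknown edit op {op!r}")
        return "".join(seq)


@dataclass
class NuclearGenome:
    """Nuclear background sequence with planted nupDNA loci and their truth."""

    sequence: str
    planted_loci: list[NupDnaTruth] = field(default_factory=list)
    name: str = "nuclear"

    @property
    def length(self) -> int:
        return len(self.sequence)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def plant_nupdna(nuclear_length: int, plastome: Plastome,
                 insertions: Sequence[NupInsertion], seed: int) -> NuclearGenome:
    """Build a nuclear sequence with plastome-derived insertions planted.

    Insertions replace evenly spaced slots of a random nuclear background so
    the total length stays ``nuclear_length``. The discriminating difference
    of ``snp``/``indel`` modes sits at the interval midpoint (0-based offset
    ``(len-1)//2`` -- the "site 80" of a 160-bp window).
    """
    rng = np.random.default_rng(seed)
    background = _random_sequence(rng, nuclear_length)
    for ins in insertions:
        if ins.source_end - ins.source_start > nuclear_length / 2:
            raise ValueError("insertion longer than half the nuclear genome")

    pieces: list[str] = []
    truths: list[NupDnaTruth] = []
    k = len(insertions)
    slot = nuclear_length // (k + 1) if k else nuclear_length
    cursor = 0
    out_pos = 0
    for i, ins in enumerate(insertions):
        src = plastome.sequence[ins.source_start:ins.source_end]
        n = len(src)
        ops: list[tuple] = []
        mid = (n - 1) // 2
        variant_offset: int | None = None
        if ins.mode == "snp":
            ops.append(("sub", mid, _other_base(rng, src[mid])))
            variant_offset = mid
        elif ins.mode == "indel":
            ops.append(("del", mid))
            variant_offset = mid
        elif ins.mode == "truncated":
            ops.append(("trunc", n // 2))
            variant_offset = n // 2  # right edge of the kept half is the junction
        if ins.identity < 1.0:
            n_sub = round((1.0 - ins.identity) * n)
            pool = [p for p in range(n) if p != mid]
            for p in rng.choice(pool, size=min(n_sub, len(pool)), replace=False):
                ops.append(("sub", int(p), _other_base(rng, src[int(p)])))
        truth = NupDnaTruth(0, 0, ins.source_start, ins.source_end, ins.mode,
                            ins.identity, variant_offset, tuple(ops))
        planted = truth.reconstruct(plastome)

        target = slot * (i + 1) - len(planted) // 2
        if target < cursor:
            raise ValueError("insertions overlap; reduce count or lengths")
        pieces.append(background[cursor:target])
        out_pos += target - cursor
        truths.append(replace(truth, nuclear_start=out_pos, nuclear_end=out_pos + len(planted)))
        pieces.append(planted)
        out_pos += len(planted)
        cursor = target + len(planted)
    pieces.append(background[cursor:])
    sequence = "".join(pieces)[:nuclear_length]
    return NuclearGenome(sequence=sequence, planted_loci=truths)
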