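"""nupDNA transcription exclusion diagnostics.

Plant nuclear genomes carry many plastome-derived insertions (nupDNAs).
Because whole-cell RNA-seq could in principle contain nupDNA transcripts,
the analysis must show that reads attributed to the plastome do not come from
them. The strategy: find plastome-homologous nuclear loci (>= 500 bp,
>= 95% identity, BLAST-style E-value screen), build 160-bp diagnostic windows
whose discriminating feature -- a SNP, a 1-bp indel, or the junction with
nuclear background -- sits at the window midpoint ("site 80", 0-based offset
79), map reads to the windows with zero mismatches, and test whether depth
collapses at the discriminating site. Reads that truly originate from the
plastome cannot match across the variant, so site-80 depth falls to zero;
transcribed nupDNAs keep it high.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import NuclearGenome, Plastome, revcomp
from .mapping import GenomeIndex, _map_one
from .simulate import ReadSet

# Karlin-Altschul parameters for +1/-2 ungapped nucleotide scoring
_LAMBDA = 1.33
_K = 0.621


@dataclass(frozen=True)
class Variant:
    offset: int          # 0-based offset within the locus (nuclear coordinates)
    kind: str            # "snp" | "indel" | "junction"


@dataclass
class NupDnaLocus:
    """A plastome-derived nuclear locus found by homology search.

    ``segments`` maps nuclear offsets to plastome offsets across indels:
    a list of ``(nuclear_offset, plastome_offset, length)`` blocks.
    """

    nuclear_start: int
    nuclear_end: int
    plastome_start: int
    plastome_end: int
    strand: str
    identity: float
    variant_positions: list[Variant] = field(default_factory=list)
    segments: list[tuple[int, int, int]] = field(default_factory=list)
    evalue: float = 0.0

    @property
    def length(self) -> int:
        return self.nuclear_end - self.nuclear_start

    def plastome_offset(self, locus_offset: int) -> Optional[int]:
        """Plastome offset homologous to a locus offset, honouring indels."""
        for n_off, p_off, seg_len in self.segments:
            if n_off <= locus_offset < n_off + seg_len:
                return p_off + (locus_offset - n_off)
        return None


@dataclass
class _Hit:
    nstart: int
    nend: int
    pstart: int
    pend: int
    mismatch_offsets: list[int]      # offsets relative to nstart

    @property
    def score(self) -> int:
        matches = (self.nend - self.nstart) - len(self.mismatch_offsets)
        return matches - 2 * len(self.mismatch_offsets)


def _extend_hit(nuc: str, pla: str, npos: int, ppos: int, k: int, xdrop: int) -> _Hit:
    """Ungapped X-drop extension of an exact k-mer seed, trimmed to max score."""
    # right extension from seed end
    score = k
    best_score, best_i = score, 0
    i = 0
    mism_r: list[int] = []
    while npos + k + i < len(nuc) and ppos + k + i < len(pla):
        score += 1 if nuc[npos + k + i] == pla[ppos + k + i] else -2
        if nuc[npos + k + i] != pla[ppos + k + i]:
            mism_r.append(i)
        i += 1
        if score > best_score:
            best_score, best_i = score, i
        if score < best_score - xdrop:
            break
    right = best_i
    mism_r = [m for m in mism_r if m < right]
    # left extension from seed start
    score = best_score
    best_j = 0
    cur = score
    j = 0
    mism_l: list[int] = []
    while npos - 1 - j >= 0 and ppos - 1 - j >= 0:
        cur += 1 if nuc[npos - 1 - j] == pla[ppos - 1 - j] else -2
        if nuc[npos - 1 - j] != pla[ppos - 1 - j]:
            mism_l.append(j)
        j += 1
        if cur > score:
            score, best_j = cur, j
        if cur < score - xdrop:
            break
    left = best_j
    mism_l = [m for m in mism_l if m < left]
    nstart = npos - left
    offsets = sorted([left - 1 - m for m in mism_l] + [left + k + m for m in mism_r])
    return _Hit(nstart=nstart, nend=npos + k + right,
                pstart=ppos - left, pend=ppos + k + right,
                mismatch_offsets=offsets)


def _find_hits(nuc: str, pla: str, k: int, xdrop: int) -> list[_Hit]:
    table: dict[str, list[int]] = {}
    for p in range(len(pla) - k + 1):
        table.setdefault(pla[p:p + k], []).append(p)
    hits: list[_Hit] = []
    seen: dict[int, list[tuple[int, int]]] = {}   # diagonal -> covered nuclear intervals
    for npos in range(0, len(nuc) - k + 1):
        for ppos in table.get(nuc[npos:npos + k], ()):
            diag = npos - ppos
            if any(s <= npos < e for s, e in seen.get(diag, ())):
                continue
            hit = _extend_hit(nuc, pla, npos, ppos, k, xdrop)
            seen.setdefault(diag, []).append((hit.nstart, hit.nend))
            hits.append(hit)
    # deduplicate identical extents found from different seeds
    uniq = {(h.nstart, h.nend, h.pstart, h.pend): h for h in hits}
    return sorted(uniq.values(), key=lambda h: h.nstart)


def _merge_hits(hits: list[_Hit], max_gap: int = 8) -> list[tuple[list[_Hit], list[Variant]]]:
    """Chain co-linear hits across small indels into locus groups."""
    groups: list[tuple[list[_Hit], list[Variant]]] = []
    for h in hits:
        if groups:
            chain, variants = groups[-1]
            last = chain[-1]
            gap_n = h.nstart - last.nend
            gap_p = h.pstart - last.pend
            # small negative gaps tolerate chance matches extending past an indel
            if (-4 <= gap_n <= max_gap and -4 <= gap_p <= max_gap
                    and h.nstart > last.nstart
                    and h.nstart - h.pstart != last.nstart - last.pstart):
                variants.append(Variant(offset=last.nend - chain[0].nstart, kind="indel"))
                chain.append(h)
                continue
        groups.append(([h], []))
    return groups


def find_nupdna(nuclear: NuclearGenome, plastome: Plastome,
                min_len: int = 500, min_identity: float = 0.95,
                evalue_cut: float = 1e-10, k: int = 16, xdrop: int = 12,
                search_reverse: bool = True) -> list[NupDnaLocus]:
    """Find plastome-derived loci in the nuclear genome.

    k-mer-seeded, ungapped X-drop extensions scored +1/-2; co-linear hits
    separated by a small indel are chained into one locus. Loci are filtered
    by length, identity and a Karlin-Altschul E-value screen, and each
    retained locus records its variant positions (SNPs, indel junctions)
    against the plastome.
    """
    results: list[NupDnaLocus] = []
    targets = [("+", plastome.sequence)]
    if search_reverse:
        targets.append(("-", revcomp(plastome.sequence)))
    area = len(nuclear.sequence) * len(plastome.sequence)
    for strand, pla in targets:
        hits = _find_hits(nuclear.sequence, pla, k, xdrop)
        for chain, variants in _merge_hits(hits):
            nstart, nend = chain[0].nstart, chain[-1].nend
            length = nend - nstart
            if length < min_len:
                continue
            n_mismatch = sum(len(h.mismatch_offsets) for h in chain)
            n_indel = len(variants)
            identity = (length - n_mismatch - n_indel) / length
            if identity < min_identity:
                continue
            score = sum(h.score for h in chain)
            evalue = _K * area * math.exp(-_LAMBDA * score)
            if evalue >= evalue_cut:
                continue
            var = sorted(
                variants + [Variant(offset=(h.nstart - nstart) + m, kind="snp")
                            for h in chain for m in h.mismatch_offsets],
                key=lambda v: v.offset)
            segments = [(h.nstart - nstart, h.pstart, h.nend - h.nstart) for h in chain]
            pstart_raw, pend_raw = chain[0].pstart, chain[-1].pend
            if strand == "+":
                pstart, pend = pstart_raw, pend_raw
            else:
                pstart = plastome.length - pend_raw
                pend = plastome.length - pstart_raw
            results.append(NupDnaLocus(
                nuclear_start=nstart, nuclear_end=nend,
                plastome_start=pstart, plastome_end=pend, strand=strand,
                identity=identity, variant_positions=var, segments=segments,
                evalue=evalue))
    results.sort(key=lambda l: (l.nuclear_start, l.nuclear_end))
    return results


@dataclass
class DiagnosticWindow:
    """A 160-bp window whose discriminating feature sits at offset ``site_offset``.

    ``sequence`` is the nuclear (nupDNA-side) window; ``paired_plastome_window``
    is the homologous plastome region used as the coverage comparator.
    """

    sequence: str
    paired_plastome_window: str
    site80_kind: str                    # "snp" | "indel" | "junction"
    nuclear_start: int
    site_offset: int = 79
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.paired_plastome_window):
            raise ValueError("window and paired plastome window must have equal length")


def build_windows(locus: NupDnaLocus, nuclear: NuclearGenome, plastome: Plastome,
                  window_len: int = 160, site_offset: int = 79,
                  include_junctions: bool = True) -> list[DiagnosticWindow]:
    """Build diagnostic windows for a locus.

    One window per interior SNP/indel variant, centered so the variant sits at
    ``site_offset`` (the 80th base); variants too close to the locus edge are
    skipped with a warning. Junction windows are built at each locus boundary
    with half the window inside the locus and half in nuclear background,
    paired with the plastome region continuing past the homologous boundary.
    Only forward-strand loci are windowed.
    """
    if locus.strand != "+":
        warnings.warn("windows are built for forward-strand loci only; skipping")
        return []
    nuc = nuclear.sequence
    pla = plastome.sequence
    right = window_len - site_offset - 1
    windows: list[DiagnosticWindow] = []
    for v in locus.variant_positions:
        if v.offset < site_offset or v.offset + right >= locus.length:
            warnings.warn(f"variant at locus offset {v.offset} too close to edge; window skipped")
            continue
        n0 = locus.nuclear_start + v.offset - site_offset
        win = nuc[n0:n0 + window_len]
        p_at = locus.plastome_offset(v.offset)
        if p_at is None:  # indel junction: homologous base is the first base after the gap
            nxt = next((s for s in locus.segments if s[0] > v.offset), None)
            p_at = nxt[1] if nxt else None
        if p_at is None:
            continue
        p0 = p_at - site_offset
        pwin = pla[p0:p0 + window_len] if 0 <= p0 and p0 + window_len <= len(pla) else None
        if pwin is None or len(win) < window_len:
            continue
        windows.append(DiagnosticWindow(sequence=win, paired_plastome_window=pwin,
                                        site80_kind=v.kind, nuclear_start=n0,
                                        site_offset=site_offset,
                                        label=f"locus@{locus.nuclear_start}:{v.kind}@{v.offset}"))
    if include_junctions:
        half = site_offset + 1
        for side, n_edge, p_edge in (("right", locus.nuclear_end, locus.plastome_end),
                                     ("left", locus.nuclear_start, locus.plastome_start)):
            n0 = n_edge - half
            p0 = p_edge - half
            if n0 < 0 or n0 + window_len > len(nuc) or p0 < 0 or p0 + window_len > len(pla):
                continue
            windows.append(DiagnosticWindow(
                sequence=nuc[n0:n0 + window_len],
                paired_plastome_window=pla[p0:p0 + window_len],
                site80_kind="junction", nuclear_start=n0, site_offset=site_offset,
                label=f"locus@{locus.nuclear_start}:junction-{side}"))
    return windows


@dataclass
class WindowProfile:
    window: DiagnosticWindow
    depth: np.ndarray             # per-offset depth on the nupDNA window
    plastome_depth: np.ndarray    # per-offset depth on the paired plastome window


def window_depth_profile(windows: Sequence[DiagnosticWindow], reads: ReadSet,
                         max_mismatch: int = 0) -> list[WindowProfile]:
    """Zero-mismatch unique mapping of reads onto each window and its pair.

    Each 160-bp window acts as a linear mini-reference; depth per window
    offset is accumulated from uniquely placed reads. The paired plastome
    window is profiled identically for comparison.
    """
    profiles: list[WindowProfile] = []
    for w in windows:
        arrays = []
        for refseq in (w.sequence, w.paired_plastome_window):
            index = GenomeIndex(refseq, circular=False, name="window")
            depth = np.zeros(len(refseq), dtype=np.int64)
            for r in reads.reads:
                aln, status = _map_one(r.sequence, index, max_mismatch)
                if status == "mapped":
                    depth[aln.position:aln.position + aln.length] += 1
            arrays.append(depth)
        profiles.append(WindowProfile(window=w, depth=arrays[0], plastome_depth=arrays[1]))
    return profiles


@dataclass
class JunctionVerdict:
    depth_at_site80: int
    flank_median_depth: float
    plastome_site_depth: int
    transcribed_verdict: Optional[bool]   # None when the plastome pair has no depth
    threshold: float


def junction_decline_stat(profile: WindowProfile, threshold: float = 0.1) -> JunctionVerdict:
    """Decide whether the locus behind a window looks transcribed.

    Verdict "transcribed" iff depth at the discriminating site exceeds
    ``threshold`` times the depth of the homologous plastome site; undefined
    (None) when the plastome pair itself has zero depth there. The threshold
    is a package choice -- no statistical test is prescribed for the decline.
    """
    s = profile.window.site_offset
    site = int(profile.depth[s])
    pla = int(profile.plastome_depth[s])
    flank_sel = np.r_[0:max(s - 30, 0), min(s + 31, profile.depth.size):profile.depth.size]
    flank = float(np.median(profile.depth[flank_sel])) if flank_sel.size else 0.0
    verdict: Optional[bool]
    if pla == 0:
        verdict = None
    else:
        verdict = site > threshold * pla
    return JunctionVerdict(depth_at_site80=site, flank_median_depth=flank,
                           plastome_site_depth=pla, transcribed_verdict=verdict,
                           threshold=threshold)


def write_loci_bed(path, loci: Sequence[NupDnaLocus], name: str = "nuclear") -> None:
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            fh.write(f"{name}\t{l.nuclear_start}\t{l.nuclear_end}\tnup{i + 1}\t"
                     f"{int(round(l.identity * 1000))}\t{l.strand}\n")


def write_loci_tsv(path, loci: Sequence[NupDnaLocus]) -> None:
    import pandas as pd
    pd.DataFrame([{
        "nuclear_start": l.nuclear_start, "nuclear_end": l.nuclear_end,
        "plastome_start": l.plastome_start, "plastome_end": l.plastome_end,
        "strand": l.strand, "length": l.length, "identity": l.identity,
        "n_variants": len(l.variant_positions), "evalue": l.evalue,
    } for l in loci]).to_csv(path, sep="\t", index=False)
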