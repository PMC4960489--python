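"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import plastoseq as ps


@pytest.fixture(scope="session")
def small_plastome() -> ps.Plastome:
    return ps.generate_plastome(ps.GenomeSpec(length=20_000, n_genes=10), seed=1)


@pytest.fixture(scope="session")
def plastome_50k() -> ps.Plastome:
    return ps.generate_plastome(ps.GenomeSpec(length=50_000, n_genes=25), seed=1)


def exhaustive_map(read_seq: str, genome: str, max_mismatch: int, circular: bool = True):
    """Brute-force all-position, all-strand Hamming scan: the mapping oracle.

    Returns (alignment_tuple_or_None, status) where the tuple is
    (position, strand, n_mismatch). Independent of the package mapper: plain
    numpy comparisons at every placement.
    """
    L = len(genome)
    rlen = len(read_seq)
    ext = genome + genome[:rlen - 1] if circular else genome
    ext_codes = np.frombuffer(ext.encode(), dtype=np.uint8)
    n_pos = L if circular else L - rlen + 1
    if n_pos <= 0:
        return None, "unmapped"
    hits = []
    for strand, seq in (("+", read_seq), ("-", ps.revcomp(read_seq))):
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        mism = np.zeros(n_pos, dtype=np.int64)
        for i, c in enumerate(codes):
            mism += ext_codes[i:i + n_pos] != c
        for p in np.flatnonzero(mism <= max_mismatch):
            hits.append((int(p), strand, int(mism[p])))
    if not hits:
        return None, "unmapped"
    best = min(h[2] for h in hits)
    best_hits = [h for h in hits if h[2] == best]
    if len(best_hits) > 1:
        return None, "multi"
    return best_hits[0], "mapped"


def read_from(genome: str, pos: int, length: int, strand: str = "+") -> str:
    """Extract a (wrap-aware) genomic substring, reverse-complemented for '-'."""
    L = len(genome)
    seq = (genome + genome)[pos:pos + length] if pos + length > L else genome[pos:pos + length]
    return ps.revcomp(seq) if strand == "-" else seq


def make_reads(seqs, quality_char="I") -> ps.ReadSet:
    return ps.ReadSet(reads=[
        ps.Read(id=f"r{i}", sequence=s, quality=quality_char * len(s))
        for i, s in enumerate(seqs)
    ])
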