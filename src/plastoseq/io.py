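"""File I/O: FASTA, GFF3-style annotation, FASTQ, bedGraph, truth JSON.

All formats are plain text. FASTA and FASTQ go through Biopython; the GFF3
writer/reader handles the nine standard columns with ``ID=`` attributes and
converts between the package's 0-based half-open coordinates and GFF's
1-based inclusive ones.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .genome import (Feature, FeatureClass, NuclearGenome, NupDnaTruth, Plastome)

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ReadSet


def write_fasta(path: str | Path, name: str, sequence: str) -> None:
    """Write one sequence as FASTA wrapped at 70 columns."""
    record = SeqRecord(Seq(sequence), id=name, description="")
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file([record])


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (name, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


_GFF_COLUMNS = ("seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes")


def write_gff(path: str | Path, plastome: Plastome) -> None:
    """Write plastome features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.name} 1 {plastome.length}\n")
        for f in plastome.features:
            attrs = f"ID={f.id}"
            if f.masked:
                attrs += ";masked=1"
            fh.write("\t".join([
                plastome.name, "plastoseq", f.feature_class.value,
                str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


def read_gff(path: str | Path) -> list[Feature]:
    """Read features from a GFF3 file written by :func:`write_gff`."""
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            features.append(Feature(
                feature_class=FeatureClass(cols[2]),
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                id=attrs.get("ID", ""),
                masked=attrs.get("masked") == "1",
            ))
    return features


def write_plastome(fasta_path: str | Path, gff_path: str | Path, plastome: Plastome) -> None:
    write_fasta(fasta_path, plastome.name, plastome.sequence)
    write_gff(gff_path, plastome)


def read_plastome(fasta_path: str | Path, gff_path: str | Path, circular: bool = True) -> Plastome:
    name, sequence = read_fasta(fasta_path)
    return Plastome(sequence=sequence, features=read_gff(gff_path), circular=circular, name=name)


def write_fastq(path: str | Path, reads: "ReadSet") -> None:
    """Write reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> "ReadSet":
    """Load a FASTQ file into a ReadSet (no simulation truth attached)."""
    from .simulate import Read, ReadSet
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        quality = "".join(chr(q + 33) for q in record.letter_annotations["phred_quality"])
        reads.append(Read(id=record.id, sequence=str(record.seq).upper(), quality=quality))
    return ReadSet(reads=reads)


def write_bedgraph(path: str | Path, name: str, depth, track_name: str = "depth") -> None:
    """Write a depth array as 4-column bedGraph (run-length compressed)."""
    import numpy as np
    depth = np.asarray(depth)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        if depth.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [depth.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{name}\t{s}\t{e}\t{int(depth[s])}\n")


def write_truth_json(path: str | Path, nuclear: NuclearGenome) -> None:
    """Persist planted nupDNA ground truth as machine-readable JSON."""
    payload = [dataclasses.asdict(t) for t in nuclear.planted_loci]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> list[NupDnaTruth]:
    payload = json.loads(Path(path).read_text())
    return [NupDnaTruth(**{**d, "edit_ops": tuple(tuple(op) for op in d["edit_ops"])})
            for d in payload]
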