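"""Reading and writing FASTA, BED6 and GFF3.

FASTA goes through Biopython; BED6 and GFF3 are plain tab-separated text
written directly.  GFF3 coordinates (1-based inclusive) are converted to the
internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import GeneAnnotation, Interval, SequenceRecord

PathLike = Union[str, Path]

_HEADER_RE = re.compile(r"(\w+)=([^\s]+)")


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    """FASTA wrapped at 60 columns; origin/species round-trip via the header."""
    bio_records = []
    for rec in records:
        desc_parts = []
        if rec.origin is not None:
            o = rec.origin
            desc_parts.append(f"origin={o.chrom}:{o.start}-{o.end}({o.strand})")
        if rec.species is not None:
            desc_parts.append(f"species={rec.species}")
        bio_records.append(
            BioSeqRecord(Seq(rec.residues), id=rec.id, description=" ".join(desc_parts))
        )
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        origin = None
        species = None
        tags = dict(_HEADER_RE.findall(bio.description))
        if "origin" in tags:
            m = re.match(r"([^:]+):(\d+)-(\d+)\(([+-])\)", tags["origin"])
            if m:
                origin = Interval(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))
        if "species" in tags:
            species = tags["species"]
        records.append(
            SequenceRecord(id=bio.id, residues=str(bio.seq), origin=origin, species=species)
        )
    return records


def write_bed(
    intervals: Iterable[Interval],
    path: PathLike,
    names: Optional[list[str]] = None,
    scores: Optional[list[float]] = None,
) -> None:
    intervals = list(intervals)
    if names is None:
        names = [f"region_{i}" for i in range(len(intervals))]
    if scores is None:
        scores = [0.0] * len(intervals)
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{int(score)}\t{iv.strand}\n")


def read_bed(path: PathLike) -> list[tuple[Interval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((Interval(chrom, start, end, strand), name, score))
    return out


def write_gff3(annotations: Iterable[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotations:
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tcisclassify\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            mrna_id = f"{gene.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tcisclassify\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{gene.strand}\t.\tID={mrna_id};Parent={gene.gene_id}\n"
            )
            for k, cds in enumerate(sorted(gene.cds_intervals, key=lambda c: c.start)):
                fh.write(
                    f"{cds.chrom}\tcisclassify\tCDS\t{cds.start + 1}\t{cds.end}\t.\t"
                    f"{gene.strand}\t0\tID={mrna_id}.cds{k};Parent={mrna_id}\n"
                )


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for chunk in field.split(";"):
        chunk = chunk.strip()
        if chunk and "=" in chunk:
            key, value = chunk.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: PathLike) -> list[GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    mrna_to_gene: dict[str, str] = {}
    cds_by_gene: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            iv = Interval(chrom, int(start) - 1, int(end), strand)
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attributes["ID"]
                genes[gid] = GeneAnnotation(gid, iv, strand, [])
                cds_by_gene.setdefault(gid, [])
            elif ftype == "mRNA":
                mrna_to_gene[attributes["ID"]] = attributes["Parent"]
            elif ftype == "CDS":
                parent = attributes["Parent"]
                gid = mrna_to_gene.get(parent, parent)
                cds_by_gene.setdefault(gid, []).append(iv)
    out = []
    for gid, gene in genes.items():
        out.append(
            GeneAnnotation(
                gid,
                gene.interval,
                gene.strand,
                sorted(cds_by_gene.get(gid, []), key=lambda c: c.start),
            )
        )
    return out
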