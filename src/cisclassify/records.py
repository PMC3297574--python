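"""Core sequence and annotation records.

All genomic intervals use the 0-based half-open convention (BED-style);
GFF3's 1-based inclusive coordinates are converted at the parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

ALPHABET = "ACGT"
_VALID = set("ACGTNacgtn")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def distance_to(self, other: "Interval") -> int:
        """Edge-to-edge distance; 0 when overlapping or adjacent."""
        if self.chrom != other.chrom:
            raise ValueError("distance between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class SequenceRecord:
    """A DNA sequence with optional genomic provenance.

    Lowercase residues denote soft-masked (repeat-like) positions; matching
    is case-insensitive, the masked fraction is a property of the record.
    """

    id: str
    residues: str
    origin: Optional[Interval] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid residues: {sorted(bad)}")
        if self.origin is not None and len(self.origin) != len(self.residues):
            raise ValueError(
                f"sequence {self.id!r}: origin span {len(self.origin)} != "
                f"residue length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gc_fraction(self) -> float:
        up = self.residues.upper()
        acgt = sum(up.count(c) for c in "ACGT")
        if acgt == 0:
            return 0.0
        return (up.count("G") + up.count("C")) / acgt

    @property
    def masked_fraction(self) -> float:
        """Fraction of lowercase (soft-masked) residues — the repeat proxy."""
        return sum(c.islower() for c in self.residues) / len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, residues=reverse_complement(self.residues))

    def subsequence(self, start: int, end: int, sub_id: Optional[str] = None) -> "SequenceRecord":
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(f"bad slice [{start}, {end}) of {self.id!r}")
        origin = None
        if self.origin is not None:
            origin = Interval(
                self.origin.chrom,
                self.origin.start + start,
                self.origin.start + end,
                self.origin.strand,
            )
        return SequenceRecord(
            id=sub_id or f"{self.id}:{start}-{end}",
            residues=self.residues[start:end],
            origin=origin,
            species=self.species,
        )


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer blocks, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(blocks):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class GeneAnnotation:
    """A gene model: outer span plus CDS blocks; introns are derived."""

    gene_id: str
    interval: Interval
    strand: str
    cds_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cds in self.cds_intervals:
            if cds.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: CDS on wrong chromosome")
            if cds.start < self.interval.start or cds.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: CDS outside gene span")

    @property
    def intron_intervals(self) -> list[Interval]:
        """Gaps between sorted exonic (CDS) blocks within the gene span."""
        blocks = merge_blocks((c.start, c.end) for c in self.cds_intervals)
        introns = []
        for (_, left_end), (right_start, _) in zip(blocks, blocks[1:]):
            if right_start > left_end:
                introns.append(
                    Interval(self.interval.chrom, left_end, right_start, self.strand)
                )
        return introns


@dataclass
class SyntheticWorld:
    """A small simulated genome with gene models and planted enhancers."""

    genome: list[SequenceRecord]
    annotations: list[GeneAnnotation]
    planted_enhancers: list[Interval]
    planted_motif_ids: list[list[str]]
    fc_gene_ids: list[str]
    signal_pwms: list
    decoy_pwms: list
    seed: int

    def chromosome(self, chrom: str) -> SequenceRecord:
        for rec in self.genome:
            if rec.id == chrom:
                return rec
        raise KeyError(f"no chromosome {chrom!r}")
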