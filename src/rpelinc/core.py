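"""Core genomic value types shared across the package.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GTF and
STAR junction I/O convert from/to their native 1-based inclusive conventions
at the file boundary, never in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An input value violates a documented invariant."""


def strands_compatible(a: str, b: str) -> bool:
    """True if two strand labels can refer to the same feature.

    An undefined strand (``.``) is compatible with either defined strand;
    this mirrors aligners that occasionally emit junctions with undefined
    strand (STAR strand code 0).
    """
    return a == b or a == "." or b == "."


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp overlap on the same chromosome; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: the region excised between two consecutive exons.

    ``intron_start`` is the first intronic base (0-based) and ``intron_end``
    one past the last, so the flanking exons end at ``intron_start`` and
    begin at ``intron_end``.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.intron_start < self.intron_end:
            raise ValidationError(
                f"intron start must be < end, got "
                f"[{self.intron_start}, {self.intron_end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def coords(self) -> tuple[str, int, int]:
        """Strand-free key used for lenient junction matching."""
        return (self.chrom, self.intron_start, self.intron_end)

    def matches(self, other: "SpliceJunction") -> bool:
        """Coordinate equality with undefined-strand leniency."""
        return self.coords == other.coords and strands_compatible(
            self.strand, other.strand
        )


@dataclass(frozen=True)
class Isoform:
    """One exon-chain transcript variant of a gene."""

    isoform_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValidationError(f"{self.isoform_id}: isoform needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.isoform_id}: exons span multiple chroms/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if not a.end <= b.start:
                raise ValidationError(
                    f"{self.isoform_id}: exons not sorted/non-overlapping "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length_bp(self) -> int:
        """Transcript length: sum of exon lengths in bases."""
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def junctions(self) -> tuple[SpliceJunction, ...]:
        """Introns between consecutive exons (empty for single-exon)."""
        return tuple(
            SpliceJunction(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def chain_signature(self) -> tuple:
        """Redundancy key: identical chains collapse regardless of gene id."""
        return (
            self.chrom,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
        )


@dataclass(frozen=True)
class ReadRecord:
    """A uniquely- or multi-mapped read as a chain of aligned blocks."""

    chrom: str
    blocks: tuple[GenomicInterval, ...]
    strand: str = "."
    unique: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValidationError("read needs >=1 aligned block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not a.end <= b.start:
                raise ValidationError("read blocks not sorted/non-overlapping")
        if len({b.chrom for b in self.blocks}) > 1:
            raise ValidationError("read blocks span multiple chroms")


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of integer half-open intervals, as a sorted disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
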