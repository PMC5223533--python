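"""Core domain types shared by every stage of the TE-landscape pipeline.

All coordinates are 0-based half-open internally.  External formats
(GFF3, RepeatMasker .out) are 1-based inclusive and converted exactly
once, at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: Compartment labels in precedence order (highest first).  Where candidate
#: regions collide during partition building, and where a TE straddles a
#: boundary with equal overlap, the earlier label wins.
LABELS: tuple[str, ...] = ("exon", "intron", "upstream", "downstream", "intergenic")

#: Labels counted as "in the gene region" (gene body).
GENIC_LABELS: tuple[str, ...] = ("exon", "intron")

#: Canonical TE classes.  Class I moves via an RNA intermediate
#: (copy-and-paste), Class II via a DNA intermediate (cut-and-paste).
TE_CLASSES: tuple[str, ...] = (
    "ClassI_LTR",
    "ClassI_LINE",
    "ClassI_SINE",
    "ClassII_DNA",
    "Other",
)

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries file/line context."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            if line is not None:
                ctx += f":{line}"
            ctx += "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open range ``[start, end)`` with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge intervals on one chromosome into disjoint sorted pieces.

    Touching intervals ([a,b) and [b,c)) are merged.  Strand of the first
    interval in each merged run is kept.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise ValidationError(f"merge_intervals expects one chromosome, got {sorted(chroms)}")
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneModel:
    """A gene span plus its (union-merged) exonic sub-intervals.

    The span may strictly contain the exons (UTR-extended annotations);
    introns are the within-span gaps between consecutive merged exons.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: exon list is empty")
        merged = tuple(merge_intervals(self.exons))
        object.__setattr__(self, "exons", merged)
        for ex in merged:
            if ex.chrom != self.span.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on {ex.chrom} but span on {self.span.chrom}"
                )
            if not self.span.contains(ex):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{ex.start},{ex.end}) outside span "
                    f"[{self.span.start},{self.span.end})"
                )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand))
        return tuple(out)


@dataclass(frozen=True)
class TECopy:
    """One annotated TE segment (one annotation record = one copy)."""

    te_id: str
    span: GenomicInterval
    te_class: str
    superfamily: str = ""
    family: str = ""
    divergence_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValidationError(
                f"te_class must be one of {TE_CLASSES}, got {self.te_class!r}"
            )
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValidationError("divergence_pct must be non-negative")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene FPKM values across a declared tissue set."""

    gene_id: str
    fpkm_by_tissue: Mapping[str, float]

    def __post_init__(self) -> None:
        for tissue, v in self.fpkm_by_tissue.items():
            if v < 0:
                raise ValidationError(
                    f"gene {self.gene_id}: negative FPKM {v} in tissue {tissue}"
                )

    @property
    def expressed(self) -> bool:
        """FPKM > 0 in any tissue."""
        return any(v > 0 for v in self.fpkm_by_tissue.values())


@dataclass(frozen=True)
class ChromosomeSpec:
    chrom: str
    length: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.length < 1:
            raise ValidationError(f"chromosome {self.chrom}: length must be >= 1")


def check_unique_chroms(chroms: Sequence[ChromosomeSpec]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for c in chroms:
        if c.chrom in lengths:
            raise ValidationError(f"duplicate chromosome {c.chrom}")
        lengths[c.chrom] = c.length
    return lengths
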