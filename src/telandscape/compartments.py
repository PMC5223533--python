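"""Decompose chromosomes into a disjoint labeled partition.

Every base of every chromosome receives exactly one label — exon, intron,
upstream flank, downstream flank, or intergenic — derived from the gene
models and a fixed flank width (default 2 kb).  Label precedence where
candidate regions collide: exon > intron > upstream > downstream >
intergenic, with the extra tie-break that where one gene's upstream flank
meets another's downstream flank, upstream wins.  Flanks are strand-aware
(upstream = 5' side) and are truncated at chromosome ends and at
higher-precedence features.  Overlapping genes are union-merged: a base is
exonic if exonic in ANY overlapping gene, else intronic.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from intervaltree import IntervalTree

from .core import (
    ChromosomeSpec,
    GeneModel,
    GenomicInterval,
    LABELS,
    ValidationError,
    check_unique_chroms,
)

DEFAULT_FLANK_BP = 2000


@dataclass(frozen=True)
class Segment:
    """One maximal run of identically-labeled bases with a fixed owner set."""

    interval: GenomicInterval
    label: str
    owners: tuple[str, ...]


@dataclass(frozen=True)
class CompartmentLengths:
    """Total bp per compartment label; conserves the genome total."""

    by_label: Mapping[str, int]
    genome_total: int

    def __post_init__(self) -> None:
        if sum(self.by_label.values()) != self.genome_total:
            raise ValidationError(
                f"compartment bp {dict(self.by_label)} do not sum to genome total "
                f"{self.genome_total}"
            )

    def genic_bp(self) -> int:
        return self.by_label.get("exon", 0) + self.by_label.get("intron", 0)


class CompartmentMap:
    """Per-chromosome sorted disjoint partition covering ``[0, length)``."""

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        segments: Mapping[str, Sequence[Segment]],
        flank_bp: int,
    ):
        self.chrom_lengths = dict(chrom_lengths)
        self.segments = {c: list(segs) for c, segs in segments.items()}
        self.flank_bp = flank_bp
        self._starts = {
            c: [s.interval.start for s in segs] for c, segs in self.segments.items()
        }
        self._validate()

    def _validate(self) -> None:
        for chrom, segs in self.segments.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"segments on unknown chromosome {chrom}")
            pos = 0
            for seg in segs:
                iv = seg.interval
                if iv.chrom != chrom:
                    raise ValidationError("segment chromosome mismatch")
                if iv.start != pos:
                    raise ValidationError(
                        f"{chrom}: gap or overlap at {pos} (segment starts {iv.start})"
                    )
                if seg.label not in LABELS:
                    raise ValidationError(f"unknown label {seg.label!r}")
                if seg.label in ("exon", "intron") and not seg.owners:
                    raise ValidationError(
                        f"{chrom}:[{iv.start},{iv.end}) {seg.label} segment has no owner gene"
                    )
                pos = iv.end
            if pos != self.chrom_lengths[chrom]:
                raise ValidationError(
                    f"{chrom}: partition covers [0,{pos}) but length is "
                    f"{self.chrom_lengths[chrom]}"
                )

    def overlapping(self, chrom: str, start: int, end: int) -> Iterator[Segment]:
        """Yield segments overlapping ``[start, end)`` on ``chrom``."""
        if chrom not in self.segments:
            raise ValidationError(f"unknown chromosome {chrom}")
        segs = self.segments[chrom]
        starts = self._starts[chrom]
        i = max(0, bisect_right(starts, start) - 1)
        while i < len(segs) and segs[i].interval.start < end:
            if segs[i].interval.end > start:
                yield segs[i]
            i += 1

    def iter_segments(self) -> Iterator[Segment]:
        for chrom in sorted(self.segments):
            yield from self.segments[chrom]

    def genic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Merged (start, end) runs labeled exon or intron on ``chrom``."""
        out: list[tuple[int, int]] = []
        for seg in self.segments.get(chrom, []):
            if seg.label in ("exon", "intron"):
                if out and out[-1][1] == seg.interval.start:
                    out[-1] = (out[-1][0], seg.interval.end)
                else:
                    out.append((seg.interval.start, seg.interval.end))
        return out


def build_compartment_map(
    genes: Sequence[GeneModel],
    chroms: Sequence[ChromosomeSpec],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> CompartmentMap:
    """Partition every chromosome into labeled compartments.

    Implementation: collect candidate feature intervals (exons, gene spans,
    strand-aware flanks) into per-label interval trees, cut each chromosome
    at every feature boundary, and classify each elementary slice by
    precedence.  Adjacent slices with identical label and owners are merged
    back into maximal segments.
    """
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    lengths = check_unique_chroms(chroms)
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in lengths}
    for g in genes:
        chrom = g.span.chrom
        if chrom not in lengths:
            raise ValidationError(f"gene {g.gene_id} on unknown chromosome {chrom}")
        if g.span.end > lengths[chrom]:
            raise ValidationError(
                f"gene {g.gene_id} span end {g.span.end} exceeds {chrom} length "
                f"{lengths[chrom]}"
            )
        by_chrom[chrom].append(g)

    segments: dict[str, list[Segment]] = {}
    for chrom, length in lengths.items():
        segments[chrom] = _partition_chromosome(chrom, length, by_chrom[chrom], flank_bp)
    return CompartmentMap(lengths, segments, flank_bp)


def _flanks(g: GeneModel, chrom_len: int, flank_bp: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream, downstream) half-open ranges, clipped to the chromosome.

    Upstream is the 5' flank: left of the span for '+' (and unknown) strand,
    right of the span for '-'.  A zero-width clipped flank is returned as
    (0, 0) and ignored by the caller.
    """
    left = (max(0, g.span.start - flank_bp), g.span.start)
    right = (g.span.end, min(chrom_len, g.span.end + flank_bp))
    if g.span.strand == "-":
        up, down = right, left
    else:
        up, down = left, right
    return up, down


def _partition_chromosome(
    chrom: str, length: int, genes: Sequence[GeneModel], flank_bp: int
) -> list[Segment]:
    exon_t, span_t, up_t, down_t = IntervalTree(), IntervalTree(), IntervalTree(), IntervalTree()
    cuts = {0, length}
    for g in genes:
        span_t.addi(g.span.start, g.span.end, g.gene_id)
        cuts.update((g.span.start, g.span.end))
        for ex in g.exons:
            exon_t.addi(ex.start, ex.end, g.gene_id)
            cuts.update((ex.start, ex.end))
        if flank_bp > 0:
            up, down = _flanks(g, length, flank_bp)
            if up[0] < up[1]:
                up_t.addi(up[0], up[1], g.gene_id)
                cuts.update(up)
            if down[0] < down[1]:
                down_t.addi(down[0], down[1], g.gene_id)
                cuts.update(down)

    bounds = sorted(c for c in cuts if 0 <= c <= length)
    raw: list[tuple[int, int, str, tuple[str, ...]]] = []
    for a, b in zip(bounds, bounds[1:]):
        if a >= b:
            continue
        mid = a  # slices never straddle a feature boundary; start point suffices
        hits = exon_t.at(mid)
        if hits:
            label, owners = "exon", {h.data for h in hits}
            # intron owners include genes covering the base non-exonically too
            owners |= {h.data for h in span_t.at(mid)}
        else:
            hits = span_t.at(mid)
            if hits:
                label, owners = "intron", {h.data for h in hits}
            else:
                hits = up_t.at(mid)
                if hits:
                    label, owners = "upstream", {h.data for h in hits}
                else:
                    hits = down_t.at(mid)
                    if hits:
                        label, owners = "downstream", {h.data for h in hits}
                    else:
                        label, owners = "intergenic", set()
        raw.append((a, b, label, tuple(sorted(owners))))

    merged: list[Segment] = []
    for a, b, label, owners in raw:
        if merged and merged[-1].label == label and merged[-1].owners == owners:
            last = merged[-1]
            merged[-1] = Segment(
                GenomicInterval(chrom, last.interval.start, b), label, owners
            )
        else:
            merged.append(Segment(GenomicInterval(chrom, a, b), label, owners))
    return merged


def compartment_lengths(cmap: CompartmentMap) -> CompartmentLengths:
    """Exact total bp per label; the conservation invariant is enforced."""
    totals = {label: 0 for label in LABELS}
    for seg in cmap.iter_segments():
        totals[seg.label] += seg.interval.length
    return CompartmentLengths(by_label=totals, genome_total=sum(cmap.chrom_lengths.values()))
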