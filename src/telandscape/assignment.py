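"""Classify TE copies into compartments and tabulate occupancy.

Each TE copy gets exactly one *primary* compartment — the label with the
largest base overlap, ties broken by the fixed precedence exon > intron >
upstream > downstream > intergenic — so compartment fractions sum to one.
A separate boolean records the any-overlap "in gene region" reading
(>= 1 bp overlapping exon or intron), which is what the depletion analyses
use.  A TE overlapping several genes is counted once in compartment totals
but listed under every owner gene for gene-level queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import GENIC_LABELS, LABELS, TECopy, ValidationError
from .compartments import CompartmentMap

#: family_te_counts column order; exon/intron collapse into "gene_region".
FAMILY_COLUMNS = ("upstream", "gene_region", "downstream")

_LABEL_TO_FAMILY_COLUMN = {
    "exon": "gene_region",
    "intron": "gene_region",
    "upstream": "upstream",
    "downstream": "downstream",
}


@dataclass(frozen=True)
class AssignmentRecord:
    te_id: str
    primary_label: str
    genic: bool  # >= 1 bp overlap with exon or intron
    owner_gene_ids: tuple[str, ...]
    overlap_bp_by_label: Mapping[str, int]
    owners_by_label: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def assign_compartment(te: TECopy, cmap: CompartmentMap) -> AssignmentRecord:
    """Compute per-label overlap of one TE against the disjoint partition."""
    overlap = {label: 0 for label in LABELS}
    owners_by_label: dict[str, set[str]] = {label: set() for label in LABELS}
    for seg in cmap.overlapping(te.span.chrom, te.span.start, te.span.end):
        bp = min(seg.interval.end, te.span.end) - max(seg.interval.start, te.span.start)
        overlap[seg.label] += bp
        owners_by_label[seg.label].update(seg.owners)
    if sum(overlap.values()) != te.span.length:
        raise ValidationError(
            f"TE {te.te_id} extends past chromosome {te.span.chrom} bounds"
        )
    best = max(overlap.values())
    primary = next(label for label in LABELS if overlap[label] == best)
    genic = (overlap["exon"] + overlap["intron"]) >= 1
    owners = tuple(sorted(set().union(*owners_by_label.values())))
    return AssignmentRecord(
        te_id=te.te_id,
        primary_label=primary,
        genic=genic,
        owner_gene_ids=owners,
        overlap_bp_by_label=overlap,
        owners_by_label={
            label: tuple(sorted(v)) for label, v in owners_by_label.items() if v
        },
    )


def assign_all(tes: Sequence[TECopy], cmap: CompartmentMap) -> list[AssignmentRecord]:
    return [assign_compartment(te, cmap) for te in tes]


@dataclass
class CompartmentCounts:
    """Occupancy tables: copies and bp per (TE class x compartment label).

    ``genic_share`` (fraction of copies whose primary label is exon or
    intron) and ``genic_share_any_overlap`` (>= 1 bp in a gene body) are
    ``None`` when there are no TEs — reported as absent, never as 0.
    """

    species_id: str
    copies: pd.DataFrame  # index: te_class (+ "total" row), columns: LABELS + total
    bp: pd.DataFrame
    genome_total_bp: int
    n_tes: int
    te_genome_fraction: float
    genic_share: Optional[float]
    genic_share_any_overlap: Optional[float]

    def to_tsv(self, copies_path, bp_path) -> None:
        self.copies.to_csv(copies_path, sep="\t")
        self.bp.to_csv(bp_path, sep="\t")


def count_by_compartment(
    assignments: Sequence[AssignmentRecord],
    tes: Sequence[TECopy],
    cmap: CompartmentMap,
    species_id: str = "",
    by: str = "te_class",
) -> CompartmentCounts:
    """Tabulate copy counts and bp per (class-or-superfamily x label).

    bp is split across labels by actual overlap; copies go entirely to the
    primary label.  Marginal consistency (every class row sums to its copy
    count) holds by construction and is asserted.
    """
    if len(assignments) != len(tes):
        raise ValidationError("assignments and tes must correspond 1:1")
    if by not in ("te_class", "superfamily"):
        raise ValidationError("by must be 'te_class' or 'superfamily'")
    groups = sorted({getattr(te, by) or "unnamed" for te in tes})
    copies = pd.DataFrame(0, index=groups, columns=list(LABELS))
    bp = pd.DataFrame(0, index=groups, columns=list(LABELS))
    for te, rec in zip(tes, assignments):
        if te.te_id != rec.te_id:
            raise ValidationError("assignments and tes must correspond 1:1")
        group = getattr(te, by) or "unnamed"
        copies.loc[group, rec.primary_label] += 1
        for label, v in rec.overlap_bp_by_label.items():
            bp.loc[group, label] += v
    copies["total"] = copies[list(LABELS)].sum(axis=1)
    bp["total"] = bp[list(LABELS)].sum(axis=1)
    copies.loc["total"] = copies.sum(axis=0)
    bp.loc["total"] = bp.sum(axis=0)
    assert int(copies.loc["total", "total"]) == len(tes)

    genome_total = sum(cmap.chrom_lengths.values())
    te_bp = _union_bp(tes)  # masked-base coverage: overlaps counted once
    n = len(tes)
    if n:
        genic_primary = sum(r.primary_label in GENIC_LABELS for r in assignments)
        genic_any = sum(r.genic for r in assignments)
        genic_share: Optional[float] = genic_primary / n
        genic_any_share: Optional[float] = genic_any / n
    else:
        genic_share = genic_any_share = None
    return CompartmentCounts(
        species_id=species_id,
        copies=copies,
        bp=bp,
        genome_total_bp=genome_total,
        n_tes=n,
        te_genome_fraction=te_bp / genome_total,
        genic_share=genic_share,
        genic_share_any_overlap=genic_any_share,
    )


def _union_bp(tes: Sequence[TECopy]) -> int:
    """Total bases covered by >= 1 TE copy (per-chromosome union merge)."""
    from .core import merge_intervals

    by_chrom: dict[str, list] = {}
    for te in tes:
        by_chrom.setdefault(te.span.chrom, []).append(te.span)
    return sum(
        iv.length
        for spans in by_chrom.values()
        for iv in merge_intervals(spans)
    )


def family_te_counts(
    assignments: Sequence[AssignmentRecord],
    gene_to_family: Mapping[str, frozenset[str] | set[str] | Sequence[str]],
) -> pd.DataFrame:
    """Per-family TE insertion counts in upstream / gene region / downstream.

    A TE contributes through the owner genes of its *primary* label, once
    per (TE, family) pair; a gene in two families increments both rows
    (documented double-count across families).  Genes absent from the map
    are ignored; intergenic TEs never contribute.
    """
    families = sorted({f for fams in gene_to_family.values() for f in fams})
    table = pd.DataFrame(0, index=families, columns=list(FAMILY_COLUMNS))
    for rec in assignments:
        col = _LABEL_TO_FAMILY_COLUMN.get(rec.primary_label)
        if col is None:
            continue
        owners = rec.owners_by_label.get(rec.primary_label, ())
        if rec.primary_label in GENIC_LABELS:
            # gene-region owners pool exon and intron ownership
            owners = tuple(
                sorted(
                    set(rec.owners_by_label.get("exon", ()))
                    | set(rec.owners_by_label.get("intron", ()))
                )
            )
        hit_families = {
            fam for g in owners for fam in gene_to_family.get(g, ())
        }
        for fam in sorted(hit_families):
            table.loc[fam, col] += 1
    return table
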