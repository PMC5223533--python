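"""Expressed / non-expressed gene stratification and the exon-intron
contingency of TE placement.

A gene is *expressed* when its FPKM is > 0 in any tissue (the RNA-seq
tissues are pooled); genes missing from the expression table default to
non-expressed, with the number of such genes reported so the caller can
audit the universe accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import ExpressionRecord, ValidationError
from .assignment import AssignmentRecord

logger = logging.getLogger(__name__)

STRATA = ("expressed", "non_expressed")
LOCATIONS = ("exon", "intron")


@dataclass(frozen=True)
class ExpressionStrata:
    expressed: frozenset[str]
    non_expressed: frozenset[str]
    tissues: tuple[str, ...]
    n_missing_from_table: int = 0

    def __post_init__(self) -> None:
        if self.expressed & self.non_expressed:
            raise ValidationError("expressed and non-expressed sets must be disjoint")

    def stratum_of(self, gene_id: str) -> str | None:
        if gene_id in self.expressed:
            return "expressed"
        if gene_id in self.non_expressed:
            return "non_expressed"
        return None


def classify_expressed(
    records: Sequence[ExpressionRecord], universe: set[str]
) -> ExpressionStrata:
    """Split the gene universe by the FPKM > 0 (any tissue) rule."""
    by_id = {}
    tissues: set[str] = set()
    for r in records:
        if r.gene_id in by_id:
            raise ValidationError(f"duplicate expression record for {r.gene_id}")
        if r.gene_id not in universe:
            raise ValidationError(f"expression record for unknown gene {r.gene_id}")
        by_id[r.gene_id] = r
        tissues.update(r.fpkm_by_tissue)
    missing = universe - set(by_id)
    if missing:
        logger.warning(
            "%d of %d genes absent from the expression table; treated as non-expressed",
            len(missing),
            len(universe),
        )
    expressed = frozenset(g for g, r in by_id.items() if r.expressed)
    return ExpressionStrata(
        expressed=expressed,
        non_expressed=frozenset(universe - expressed),
        tissues=tuple(sorted(tissues)),
        n_missing_from_table=len(missing),
    )


@dataclass(frozen=True)
class StratifiedTable:
    """TE counts by (stratum x exon/intron) plus genes-with-TE per stratum.

    ``n_multi_stratum_duplicates`` counts the extra contributions made by
    TEs whose owner genes span both strata, so the conservation check
    ``sum(counts) = genic primary TEs + duplicates`` is auditable.
    """

    counts: pd.DataFrame  # index STRATA, columns LOCATIONS
    genes_with_te: dict[str, int]
    n_multi_stratum_duplicates: int

    def as_2x2(self) -> list[list[int]]:
        return [[int(self.counts.loc[s, l]) for l in LOCATIONS] for s in STRATA]


def stratified_exon_intron_counts(
    assignments: Sequence[AssignmentRecord],
    strata: ExpressionStrata,
) -> StratifiedTable:
    """Cross-tabulate exon/intron TEs against owner-gene expression strata.

    Only TEs whose *primary* label is exon or intron contribute.  A TE owned
    by genes in both strata contributes once to each stratum's cell (the
    duplication is counted and reported).
    """
    counts = pd.DataFrame(0, index=list(STRATA), columns=list(LOCATIONS))
    genes_with_te: dict[str, set[str]] = {s: set() for s in STRATA}
    duplicates = 0
    for rec in assignments:
        if rec.primary_label not in LOCATIONS:
            continue
        owners = set(rec.owners_by_label.get("exon", ())) | set(
            rec.owners_by_label.get("intron", ())
        )
        hit_strata = {s for s in (strata.stratum_of(g) for g in owners) if s}
        if len(hit_strata) > 1:
            duplicates += len(hit_strata) - 1
        for s in hit_strata:
            counts.loc[s, rec.primary_label] += 1
            for g in owners:
                if strata.stratum_of(g) == s:
                    genes_with_te[s].add(g)
    return StratifiedTable(
        counts=counts,
        genes_with_te={s: len(genes_with_te[s]) for s in STRATA},
        n_multi_stratum_duplicates=duplicates,
    )
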