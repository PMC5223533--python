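"""Readers and writers for every external format the pipeline touches.

Formats handled: GFF3 gene annotations (via :mod:`gffutils`), RepeatMasker
``.out`` repeat tables, TSV expression tables (gene x tissue FPKM),
two-column chromosome-length files, two-column gene->term / gene->family
maps, and BED output.  All coordinates are converted to the internal
0-based half-open convention exactly once, here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd

from .core import (
    ChromosomeSpec,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    ParseError,
    TECopy,
    ValidationError,
)

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# TE class mapping
# ---------------------------------------------------------------------------

#: Repeat class/family string -> canonical TE class, matched by prefix in
#: order.  Repbase/RepeatMasker vocabularies drift, so this table is plain
#: data and can be extended or replaced by callers.
DEFAULT_CLASS_MAP: tuple[tuple[str, str], ...] = (
    ("LTR", "ClassI_LTR"),
    ("LINE", "ClassI_LINE"),
    ("SINE", "ClassI_SINE"),
    ("DNA", "ClassII_DNA"),
    ("RC", "ClassII_DNA"),  # rolling-circle Helitrons: DNA intermediate
    ("MULE", "ClassII_DNA"),
    ("En-Spm", "ClassII_DNA"),
    ("EnSpm", "ClassII_DNA"),
    ("CMC", "ClassII_DNA"),
    ("hAT", "ClassII_DNA"),
    ("TcMar", "ClassII_DNA"),
    ("PIF", "ClassII_DNA"),
    ("Harbinger", "ClassII_DNA"),
    ("Mutator", "ClassII_DNA"),
)

#: Repeat classes dropped by default: not transposable elements (the paper's
#: annotation ran with simple/low-complexity and structural RNA masking off).
NON_TE_CLASSES: frozenset[str] = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "srpRNA",
        "scRNA",
        "ncRNA",
        "Artefact",
    }
)


def classify_repeat(
    class_family: str,
    class_map: Sequence[tuple[str, str]] = DEFAULT_CLASS_MAP,
) -> tuple[str, str]:
    """Map a RepeatMasker class/family string to ``(te_class, superfamily)``.

    ``"LTR/Gypsy"`` -> ``("ClassI_LTR", "Gypsy")``; an unmatched string maps
    to ``("Other", <string>)``.  The superfamily is the part after the first
    ``/`` when present, else the whole token.
    """
    head = class_family.split("/", 1)[0]
    superfamily = class_family.split("/", 1)[1] if "/" in class_family else class_family
    for prefix, te_class in class_map:
        if head.startswith(prefix):
            return te_class, superfamily
    return "Other", superfamily


def is_te_class_string(class_family: str) -> bool:
    """False for simple repeats, satellites, low-complexity and RNA genes."""
    head = class_family.split("/", 1)[0]
    return head not in NON_TE_CLASSES


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeaturePolicy:
    """Which GFF3 feature types constitute genes and exons."""

    gene_types: tuple[str, ...] = ("gene",)
    exon_types: tuple[str, ...] = ("exon",)


def read_gff3_genes(
    path: PathLike,
    feature_policy: FeaturePolicy = FeaturePolicy(),
) -> list[GeneModel]:
    """Read gene models from GFF3.

    Exons of all transcripts of a gene are union-merged into one exon chain
    per gene.  GFF3 1-based inclusive coordinates become 0-based half-open.
    An exon whose ``Parent`` chain does not resolve to a known feature is a
    :class:`ParseError`; an exon outside its gene's span is a
    :class:`ValidationError` (raised by :class:`GeneModel`).
    """
    path = str(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_ids = {f.id for f in db.all_features()}
    known_ids |= {
        pid for f in db.all_features() for pid in f.attributes.get("ID", [])
    }
    for feat in db.all_features():
        if feat.featuretype in feature_policy.exon_types:
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise ParseError(
                    f"exon feature has no Parent attribute", path=path, line=feat.start
                )
            for pid in parents:
                if pid not in known_ids:
                    raise ParseError(
                        f"exon Parent {pid!r} does not resolve to any feature",
                        path=path,
                        line=feat.start,
                    )

    genes: list[GeneModel] = []
    for gtype in feature_policy.gene_types:
        for g in db.features_of_type(gtype, order_by=("seqid", "start")):
            span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
                for e in db.children(g, featuretype=feature_policy.exon_types)
            ]
            if not exons:
                raise ParseError(
                    f"gene {g.id} has no exon children", path=path, line=g.start
                )
            genes.append(GeneModel(gene_id=g.id, span=span, exons=tuple(exons)))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: PathLike) -> None:
    """Emit gene/mRNA/exon GFF3 (one synthetic transcript per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            s = g.span
            strand = s.strand if s.strand != "." else "."
            fh.write(
                f"{s.chrom}\ttelandscape\tgene\t{s.start + 1}\t{s.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{s.chrom}\ttelandscape\tmRNA\t{s.start + 1}\t{s.end}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{s.chrom}\ttelandscape\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query           matching"
    "       repeat              position in repeat\n"
    "score  div. del. ins.  sequence  begin  end        (left)    repeat"
    "         class/family      begin  end    (left)   ID\n"
)


def read_repeatmasker_out(
    path: PathLike,
    class_map: Sequence[tuple[str, str]] = DEFAULT_CLASS_MAP,
    exclude_simple: bool = True,
) -> list[TECopy]:
    """Read a RepeatMasker ``.out`` table into TE copies.

    Each record is one copy — fragments are *not* rejoined via the ID
    column.  Strand ``C`` (complement) maps to ``-``.  Query coordinates are
    1-based inclusive.  Simple repeats / satellites / low-complexity /
    structural-RNA records are dropped when ``exclude_simple`` (default).
    """
    path = str(path)
    tes: list[TECopy] = []
    n = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            # header lines start with "SW"/"score"; data rows with a score
            if not fields[0].lstrip("-").isdigit():
                continue
            if len(fields) < 14:
                raise ParseError(
                    f"RepeatMasker record has {len(fields)} fields, need >= 14",
                    path=path,
                    line=lineno,
                )
            try:
                div = float(fields[1])
                chrom = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"malformed numeric field: {exc}", path=path, line=lineno)
            if qbegin > qend:
                raise ValidationError(
                    f"query begin {qbegin} > end {qend} at {path}:{lineno}"
                )
            strand = "-" if fields[8] == "C" else "+"
            rep_name = fields[9]
            class_family = fields[10]
            if exclude_simple and not is_te_class_string(class_family):
                continue
            te_class, superfamily = classify_repeat(class_family, class_map)
            n += 1
            tes.append(
                TECopy(
                    te_id=f"te{n}",
                    span=GenomicInterval(chrom, qbegin - 1, qend, strand),
                    te_class=te_class,
                    superfamily=superfamily,
                    family=rep_name,
                    divergence_pct=div,
                )
            )
    return tes


def write_repeatmasker_out(tes: Sequence[TECopy], path: PathLike) -> None:
    """Emit TE copies in parseable RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        fh.write("\n")
        for i, te in enumerate(
            sorted(tes, key=lambda t: (t.span.chrom, t.span.start, t.te_id)), start=1
        ):
            s = te.span
            strand = "C" if s.strand == "-" else "+"
            div = te.divergence_pct if te.divergence_pct is not None else 0.0
            class_family = _class_family_string(te)
            fh.write(
                f"{1000:>5} {div:4.1f}  0.0  0.0  {s.chrom} {s.start + 1} {s.end} "
                f"(0) {strand} {te.family or te.superfamily or 'unknown'} "
                f"{class_family} 1 {s.length} (0) {i}\n"
            )


def _class_family_string(te: TECopy) -> str:
    prefix = {
        "ClassI_LTR": "LTR",
        "ClassI_LINE": "LINE",
        "ClassI_SINE": "SINE",
        "ClassII_DNA": "DNA",
        "Other": "Unknown",
    }[te.te_class]
    if te.superfamily and te.superfamily != prefix:
        return f"{prefix}/{te.superfamily}"
    return prefix


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------


def read_expression_table(path: PathLike) -> list[ExpressionRecord]:
    """TSV with header ``gene_id<TAB>tissue1<TAB>...``; one record per gene."""
    path = str(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError("expression table needs gene_id plus >=1 tissue column", path=path)
    gene_col = df.columns[0]
    tissues = list(df.columns[1:])
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene_id in expression table: {dup.iloc[0]}")
    records: list[ExpressionRecord] = []
    for _, row in df.iterrows():
        vals = {}
        for t in tissues:
            try:
                v = float(row[t])
            except (TypeError, ValueError):
                raise ParseError(
                    f"malformed FPKM value {row[t]!r} for gene {row[gene_col]}", path=path
                )
            vals[t] = v
        records.append(ExpressionRecord(gene_id=str(row[gene_col]), fpkm_by_tissue=vals))
    return records


def write_expression_table(
    records: Sequence[ExpressionRecord], tissues: Sequence[str], path: PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *tissues])
        for r in sorted(records, key=lambda r: r.gene_id):
            w.writerow([r.gene_id] + [repr(float(r.fpkm_by_tissue.get(t, 0.0))) for t in tissues])


# ---------------------------------------------------------------------------
# Chromosome lengths, gene maps, BED
# ---------------------------------------------------------------------------


def read_chrom_lengths(path: PathLike) -> list[ChromosomeSpec]:
    """Two-column text: chromosome name, length in bp."""
    path = str(path)
    out: list[ChromosomeSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("expected two columns: chrom length", path=path, line=lineno)
            chrom = fields[0]
            if chrom in seen:
                raise ValidationError(f"duplicate chromosome {chrom} at {path}:{lineno}")
            seen.add(chrom)
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer length {fields[1]!r}", path=path, line=lineno)
            out.append(ChromosomeSpec(chrom, length))
    return out


def write_chrom_lengths(chroms: Sequence[ChromosomeSpec], path: PathLike) -> None:
    with open(path, "w") as fh:
        for c in sorted(chroms, key=lambda c: c.chrom):
            fh.write(f"{c.chrom}\t{c.length}\n")


def read_gene_map(path: PathLike) -> dict[str, frozenset[str]]:
    """Two-column TSV ``gene_id<TAB>label`` (one pair per row) -> gene to
    label-set mapping.  Used for gene->GO-term and gene->family maps."""
    path = str(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected two tab-separated columns", path=path, line=lineno)
            mapping.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(v) for g, v in mapping.items()}


def write_gene_map(mapping: Mapping[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for label in sorted(mapping[gene]):
                fh.write(f"{gene}\t{label}\n")


def write_bed(
    intervals: Sequence[tuple[GenomicInterval, str]], path: PathLike
) -> None:
    """Write labeled intervals as BED (name column = label).

    Rows are ordered deterministically by (chrom, start, end, name).  When
    any interval carries strand information, BED6 columns (score 0, strand)
    are appended to every row.
    """
    rows = sorted(intervals, key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[1]))
    with_strand = any(iv.strand != "." for iv, _ in rows)
    with open(path, "w") as fh:
        for iv, label in rows:
            if with_strand:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")
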