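"""Synthetic genomes, TE landscapes, expression tables and term maps with
known ground truth.

The generator emulates the statistical structure the pipeline analyses:
multi-chromosome genomes; non-overlapping genes with exon/intron structure
and 2-kb flanks; TE copies of the five canonical classes with long-tailed
(log-normal) length distributions, LTR elements longest; a compartment
placement bias — the depletion factor ``delta`` scales the probability that
a copy lands in a gene body relative to the length-proportional chance
expectation (``delta`` near 1 emulates wild genomes, ``delta`` < 1
cultivated ones), and the intron bias ``beta`` scales intron-vs-exon
placement inside *expressed* genes; zero-inflated tissue FPKM values; and a
gene->term map with one planted enriched term.

Placement semantics: each copy first draws its compartment category —
gene-body with probability ``delta * g`` (g = genic bp fraction of the
genome), otherwise a non-genic label in proportion to bp — then a length,
then a uniform position among the starts that keep the copy inside a single
segment of that category.  The genic indicator is therefore exactly
Bernoulli(delta * g) per copy, so the observed/expected genic ratio is an
unbiased estimator of ``delta``.  Every generator is fully deterministic
under the SyntheticSpec seed; each stage uses its own spawned stream so the pieces
are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as tio
from .compartments import CompartmentMap, build_compartment_map, compartment_lengths
from .core import (
    ChromosomeSpec,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    TECopy,
    ValidationError,
)

MIN_EXON_BP = 50
MIN_INTRON_BP = 60
MIN_GENE_GAP_BP = 150
MIN_TE_BP = 50

#: (superfamily, weight) choices within each TE class.
_SUPERFAMILIES: dict[str, tuple[tuple[str, float], ...]] = {
    "ClassI_LTR": (("Gypsy", 0.65), ("Copia", 0.35)),
    "ClassI_LINE": (("L1", 1.0),),
    "ClassI_SINE": (("tRNA", 1.0),),
    "ClassII_DNA": (("MULE-MuDR", 0.4), ("En-Spm", 0.3), ("hAT", 0.3)),
    "Other": (("Unknown", 1.0),),
}

#: log-normal (mean-log, sigma-log) fragment lengths per class, bp.  LTR
#: fragments get the longest median, SINEs the shortest; medians reflect
#: RepeatMasker fragments (mean overall ~500 bp), not full-length elements.
_TE_LENGTH_PARAMS: dict[str, tuple[float, float]] = {
    "ClassI_LTR": (np.log(800.0), 0.8),
    "ClassI_LINE": (np.log(500.0), 0.8),
    "ClassI_SINE": (np.log(180.0), 0.4),
    "ClassII_DNA": (np.log(250.0), 0.7),
    "Other": (np.log(250.0), 0.7),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (1, 8)
    exon_length_lognorm: tuple[float, float] = (float(np.log(200.0)), 0.6)
    intron_length_lognorm: tuple[float, float] = (float(np.log(400.0)), 0.7)
    flank_bp: int = 2000
    n_tes: int = 1200
    te_class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "ClassI_LTR": 0.30,
            "ClassI_LINE": 0.07,
            "ClassI_SINE": 0.03,
            "ClassII_DNA": 0.45,
            "Other": 0.15,
        }
    )
    delta: float = 1.0  # gene-body depletion factor
    beta: float = 1.0  # intron-vs-exon bias inside expressed genes
    expressed_fraction: float = 0.6
    tissues: tuple[str, ...] = ("leaf", "panicle", "root")
    n_background_terms: int = 30
    term_base_prob: float = 0.08
    planted_term: str = "GO:0016301"
    planted_fold: float = 4.0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValidationError("need >= 1 chromosome of positive length")
        if self.n_genes < 0 or self.n_tes < 0:
            raise ValidationError("counts must be non-negative")
        if self.delta < 0 or self.beta <= 0:
            raise ValidationError("delta must be >= 0 and beta > 0")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValidationError("expressed_fraction must lie in [0, 1]")
        mix = sum(self.te_class_mixture.values())
        if not np.isclose(mix, 1.0):
            raise ValidationError(f"te_class_mixture sums to {mix}, must be 1")


@dataclass
class TruthRecord:
    """Realized ground truth, kept consistent with the emitted files."""

    delta: float
    beta: float
    expressed_genes: frozenset[str]
    category_counts: dict[str, int]  # placement category -> copies
    genic_te_count: int
    expected_genic_probability: float  # delta * g actually used
    planted_term: str
    planted_fold: float
    planted_term_genes: frozenset[str] = frozenset()
    genic_te_genes: frozenset[str] = frozenset()


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    chroms: list[ChromosomeSpec]
    genes: list[GeneModel]
    cmap: CompartmentMap
    tes: list[TECopy]
    expression: list[ExpressionRecord]
    gene_to_terms: dict[str, frozenset[str]]
    truth: TruthRecord
    paths: dict[str, Path] = field(default_factory=dict)


def _stage_rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def _lognormal_int(rng: np.random.Generator, mu: float, sigma: float, lo: int) -> int:
    return max(lo, int(round(rng.lognormal(mu, sigma))))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(spec: SyntheticSpec) -> tuple[list[GeneModel], list[ChromosomeSpec]]:
    """Draw non-overlapping genes with exon/intron structure.

    Genes are spread round-robin over chromosomes.  Per chromosome the gene
    bodies are laid out left-to-right with random inter-gene gaps obtained
    by splitting the residual length multinomially — an exact feasibility
    check, so an infeasible density raises instead of looping.
    """
    rng = _stage_rng(spec, 1)
    chroms = [
        ChromosomeSpec(f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chroms)
    ]
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        structures = []
        lo, hi = spec.exons_per_gene
        for _ in range(n_here):
            n_ex = int(rng.integers(lo, hi + 1))
            ex_lens = [
                _lognormal_int(rng, *spec.exon_length_lognorm, MIN_EXON_BP)
                for _ in range(n_ex)
            ]
            in_lens = [
                _lognormal_int(rng, *spec.intron_length_lognorm, MIN_INTRON_BP)
                for _ in range(n_ex - 1)
            ]
            structures.append((ex_lens, in_lens))
        total_gene_bp = sum(sum(e) + sum(i) for e, i in structures)
        n_gaps = n_here + 1
        slack = chrom.length - total_gene_bp - n_gaps * MIN_GENE_GAP_BP
        if slack < 0:
            raise ValidationError(
                f"{chrom.chrom}: gene density infeasible "
                f"({total_gene_bp} gene bp + gaps exceed {chrom.length} bp)"
            )
        extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
        pos = 0
        for (ex_lens, in_lens), gap_extra in zip(structures, extra[:-1]):
            pos += MIN_GENE_GAP_BP + int(gap_extra)
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = pos
            for i, ex_len in enumerate(ex_lens):
                exons.append(GenomicInterval(chrom.chrom, cursor, cursor + ex_len, strand))
                cursor += ex_len
                if i < len(in_lens):
                    cursor += in_lens[i]
            span = GenomicInterval(chrom.chrom, pos, cursor, strand)
            genes.append(GeneModel(f"g{gid:05d}", span, tuple(exons)))
            pos = cursor
    return genes, chroms


def choose_expressed(spec: SyntheticSpec, gene_ids: Sequence[str]) -> frozenset[str]:
    """Pick exactly round(fraction * n) genes as the expressed truth set."""
    rng = _stage_rng(spec, 2)
    n_expr = int(round(spec.expressed_fraction * len(gene_ids)))
    chosen = rng.choice(sorted(gene_ids), size=n_expr, replace=False)
    return frozenset(str(g) for g in chosen)


# ---------------------------------------------------------------------------
# TE landscape
# ---------------------------------------------------------------------------


class _CategoryPool:
    """Segments of one placement category, sampled by available start count."""

    def __init__(self, segments: list[tuple[str, int, int]]):
        self.segments = segments  # (chrom, start, end)
        self.lengths = np.array([e - s for _, s, e in segments], dtype=np.int64)
        self.max_len = int(self.lengths.max()) if segments else 0
        self.total_bp = int(self.lengths.sum())

    def place(self, rng: np.random.Generator, te_len: int) -> tuple[str, int]:
        slots = self.lengths - te_len + 1
        slots = np.where(slots > 0, slots, 0)
        total = int(slots.sum())
        if total == 0:
            raise ValidationError("no segment can hold this TE")
        idx = int(rng.choice(len(self.segments), p=slots / total))
        chrom, s, e = self.segments[idx]
        start = int(s + rng.integers(0, slots[idx]))
        return chrom, start


def plant_te_landscape(
    spec: SyntheticSpec,
    cmap: CompartmentMap,
    expressed: frozenset[str],
) -> tuple[list[TECopy], TruthRecord]:
    """Place TE copies with the delta / beta compartment bias.

    Category probabilities: gene body with probability ``delta * g``
    (error if > 1), split exon-vs-intron by bp with intron weight
    multiplied by ``beta`` inside expressed genes; the remaining mass goes
    to upstream / downstream / intergenic in proportion to their bp.  A
    drawn length that fits no segment of its category is redrawn (bounded),
    keeping the category — and hence the genic indicator — intact.
    """
    rng = _stage_rng(spec, 3)
    pools: dict[str, list[tuple[str, int, int]]] = {
        "exon_expr": [],
        "exon_non": [],
        "intron_expr": [],
        "intron_non": [],
        "upstream": [],
        "downstream": [],
        "intergenic": [],
    }
    for seg in cmap.iter_segments():
        iv = seg.interval
        if seg.label in ("exon", "intron"):
            expr = any(g in expressed for g in seg.owners)
            key = f"{seg.label}_{'expr' if expr else 'non'}"
            pools[key].append((iv.chrom, iv.start, iv.end))
        else:
            pools[seg.label].append((iv.chrom, iv.start, iv.end))
    cat_pools = {k: _CategoryPool(v) for k, v in pools.items()}

    clens = compartment_lengths(cmap)
    g_frac = clens.genic_bp() / clens.genome_total
    p_genic = spec.delta * g_frac
    if p_genic > 1.0:
        raise ValidationError(
            f"delta={spec.delta} with genic fraction {g_frac:.3f} gives "
            "gene-body probability > 1"
        )

    genic_keys = ["exon_expr", "exon_non", "intron_expr", "intron_non"]
    genic_w = np.array(
        [
            cat_pools["exon_expr"].total_bp,
            cat_pools["exon_non"].total_bp,
            cat_pools["intron_expr"].total_bp * spec.beta,
            cat_pools["intron_non"].total_bp,
        ],
        dtype=float,
    )
    nong_keys = ["upstream", "downstream", "intergenic"]
    nong_w = np.array([cat_pools[k].total_bp for k in nong_keys], dtype=float)
    if p_genic > 0 and genic_w.sum() == 0:
        raise ValidationError("delta > 0 but the genome has no gene bodies")
    if p_genic < 1 and nong_w.sum() == 0:
        raise ValidationError("no non-genic bases to place TEs in")

    classes = sorted(spec.te_class_mixture)
    class_p = np.array([spec.te_class_mixture[c] for c in classes])
    category_counts = {k: 0 for k in genic_keys + nong_keys}
    tes: list[TECopy] = []
    genic_count = 0
    for i in range(spec.n_tes):
        te_class = classes[int(rng.choice(len(classes), p=class_p))]
        sf_choices = _SUPERFAMILIES[te_class]
        sf = sf_choices[
            int(rng.choice(len(sf_choices), p=[w for _, w in sf_choices]))
        ][0]
        family = f"{sf}-{int(rng.integers(1, 11))}"
        if rng.random() < p_genic:
            keys, weights = genic_keys, genic_w
            genic_count += 1
        else:
            keys, weights = nong_keys, nong_w
        key = keys[int(rng.choice(len(keys), p=weights / weights.sum()))]
        pool = cat_pools[key]
        mu, sigma = _TE_LENGTH_PARAMS[te_class]
        te_len = None
        for _ in range(200):
            cand = _lognormal_int(rng, mu, sigma, MIN_TE_BP)
            if cand <= pool.max_len:
                te_len = cand
                break
        if te_len is None:
            raise ValidationError(
                f"no segment of category {key} can hold a {te_class} copy "
                f"after bounded retries"
            )
        chrom, start = pool.place(rng, te_len)
        category_counts[key] += 1
        tes.append(
            TECopy(
                te_id=f"te{i + 1}",
                span=GenomicInterval(chrom, start, start + te_len, "+" if rng.random() < 0.5 else "-"),
                te_class=te_class,
                superfamily=sf,
                family=family,
                divergence_pct=float(np.round(rng.uniform(0.5, 35.0), 1)),
            )
        )
    truth = TruthRecord(
        delta=spec.delta,
        beta=spec.beta,
        expressed_genes=expressed,
        category_counts=category_counts,
        genic_te_count=genic_count,
        expected_genic_probability=p_genic,
        planted_term=spec.planted_term,
        planted_fold=spec.planted_fold,
    )
    return tes, truth


# ---------------------------------------------------------------------------
# Expression and term map
# ---------------------------------------------------------------------------


def generate_expression(
    spec: SyntheticSpec,
    gene_ids: Sequence[str],
    expressed: frozenset[str],
) -> list[ExpressionRecord]:
    """Zero-inflated FPKM table: expressed genes get log-normal FPKM in at
    least one tissue (per-tissue dropout), non-expressed genes all zeros."""
    rng = _stage_rng(spec, 4)
    records = []
    for g in sorted(gene_ids):
        vals = {t: 0.0 for t in spec.tissues}
        if g in expressed:
            on = rng.random(len(spec.tissues)) > 0.3
            if not on.any():
                on[int(rng.integers(0, len(spec.tissues)))] = True
            for t, flag in zip(spec.tissues, on):
                if flag:
                    vals[t] = float(np.round(rng.lognormal(np.log(5.0), 1.2), 4))
        records.append(ExpressionRecord(g, vals))
    return records


def generate_term_map(
    spec: SyntheticSpec,
    gene_ids: Sequence[str],
    genic_te_genes: frozenset[str],
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Uniform background terms plus one planted term oversampling
    genic-TE genes by ``planted_fold``.  Returns (map, planted-term genes)."""
    rng = _stage_rng(spec, 5)
    if spec.n_background_terms == 0 and spec.planted_fold == 0:
        return {}, frozenset()
    mapping: dict[str, set[str]] = {}
    p0 = spec.term_base_prob
    p_planted_hit = min(1.0, spec.planted_fold * p0)
    planted_members: set[str] = set()
    for g in sorted(gene_ids):
        terms = set()
        draws = rng.random(spec.n_background_terms)
        for j in np.nonzero(draws < p0)[0]:
            terms.add(f"GO:{j + 1:07d}")
        p_hit = p_planted_hit if g in genic_te_genes else p0
        if rng.random() < p_hit:
            terms.add(spec.planted_term)
            planted_members.add(g)
        if terms:
            mapping[g] = frozenset(terms)
    return mapping, frozenset(planted_members)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def simulate_dataset(
    spec: SyntheticSpec, outdir: Optional[Path | str] = None
) -> SyntheticDataset:
    """Run every generator stage; optionally write the full file bundle.

    Emits exactly the formats the readers consume (GFF3 genes, RepeatMasker
    .out TEs, chromosome lengths, expression TSV, gene->term TSV), so
    write-then-read round-trips are themselves a pipeline test.
    """
    genes, chroms = generate_genome(spec)
    cmap = build_compartment_map(genes, chroms, flank_bp=spec.flank_bp)
    gene_ids = [g.gene_id for g in genes]
    expressed = choose_expressed(spec, gene_ids)
    tes, truth = plant_te_landscape(spec, cmap, expressed)

    from .assignment import assign_all

    assignments = assign_all(tes, cmap)
    genic_te_genes = frozenset(
        g
        for rec in assignments
        if rec.primary_label in ("exon", "intron")
        for g in rec.owner_gene_ids
    )
    expression = generate_expression(spec, gene_ids, expressed)
    gene_to_terms, planted_members = generate_term_map(spec, gene_ids, genic_te_genes)
    truth.genic_te_genes = genic_te_genes
    truth.planted_term_genes = planted_members

    ds = SyntheticDataset(
        spec=spec,
        chroms=chroms,
        genes=genes,
        cmap=cmap,
        tes=tes,
        expression=expression,
        gene_to_terms=gene_to_terms,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_gff3": outdir / "genes.gff3",
            "chrom_lengths": outdir / "chrom_lengths.tsv",
            "te_out": outdir / "tes.out",
            "expression": outdir / "expression.tsv",
            "gene_terms": outdir / "gene_terms.tsv",
        }
        tio.write_gff3_genes(genes, paths["genes_gff3"])
        tio.write_chrom_lengths(chroms, paths["chrom_lengths"])
        tio.write_repeatmasker_out(tes, paths["te_out"])
        tio.write_expression_table(expression, list(spec.tissues), paths["expression"])
        tio.write_gene_map(gene_to_terms, paths["gene_terms"])
        ds.paths = paths
    return ds
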