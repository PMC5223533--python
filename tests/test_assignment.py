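"""te_assignment: primary-label logic, tallies, family tables, oracle checks."""

import numpy as np
import pytest

from telandscape.core import GenomicInterval, TECopy
from telandscape.assignment import (
    assign_all,
    assign_compartment,
    count_by_compartment,
    family_te_counts,
)
from telandscape.compartments import build_compartment_map, compartment_lengths
from telandscape.simulate import SyntheticSpec, generate_genome, simulate_dataset

import oracles


def _te(chrom, start, end, te_id="t1", te_class="ClassII_DNA"):
    return TECopy(te_id, GenomicInterval(chrom, start, end, "+"), te_class)


def test_te_inside_exon_is_exonic_and_genic(single_gene_cmap):
    rec = assign_compartment(_te("chr1", 5500, 5600), single_gene_cmap)
    assert rec.primary_label == "exon"
    assert rec.genic
    assert rec.owner_gene_ids == ("gA",)
    assert sum(rec.overlap_bp_by_label.values()) == 100


def test_boundary_tie_breaks_toward_exon(single_gene_cmap):
    rec = assign_compartment(_te("chr1", 4500, 5500), single_gene_cmap)
    assert rec.overlap_bp_by_label["upstream"] == 500
    assert rec.overlap_bp_by_label["exon"] == 500
    assert rec.primary_label == "exon"


def test_one_bp_gene_overlap_sets_genic_flag(single_gene_cmap):
    rec = assign_compartment(_te("chr1", 3500, 5001), single_gene_cmap)
    assert rec.primary_label == "upstream"
    assert rec.genic  # any-overlap gene-region reading


def test_genic_share_simple_counts(single_gene_cmap):
    tes = [
        _te("chr1", 5100, 5200, "t1"),  # exon
        _te("chr1", 10000, 10100, "t2"),  # intergenic
        _te("chr1", 11000, 11100, "t3"),  # intergenic
        _te("chr1", 5400, 5500, "t4"),  # exon
    ]
    recs = assign_all(tes, single_gene_cmap)
    counts = count_by_compartment(recs, tes, single_gene_cmap)
    assert counts.genic_share == 0.5
    assert int(counts.copies.loc["total", "total"]) == 4


def test_zero_tes_report_absent_genic_share(single_gene_cmap):
    counts = count_by_compartment([], [], single_gene_cmap)
    assert counts.n_tes == 0
    assert counts.genic_share is None
    assert counts.genic_share_any_overlap is None


@pytest.mark.parametrize("seed", [5, 6])
def test_assignment_matches_per_base_oracle(seed):
    """Primary labels and bp overlaps equal brute-force per-base counting."""
    spec = SyntheticSpec(
        seed=seed, n_chroms=1, chrom_length=100_000, n_genes=20, n_tes=0
    )
    genes, chroms = generate_genome(spec)
    cmap = build_compartment_map(genes, chroms, flank_bp=2000)
    arr = oracles.per_base_labels(genes, "chr1", 100_000, 2000)
    rng = np.random.default_rng(seed)
    for i in range(400):
        length = int(rng.integers(50, 4000))
        start = int(rng.integers(0, 100_000 - length))
        rec = assign_compartment(_te("chr1", start, start + length, f"t{i}"), cmap)
        assert rec.overlap_bp_by_label == oracles.per_base_overlaps(
            arr, start, start + length
        )
        assert rec.primary_label == oracles.per_base_primary(arr, start, start + length)


def test_copy_count_conservation_per_class(neutral_dataset):
    ds = neutral_dataset
    recs = assign_all(ds.tes, ds.cmap)
    counts = count_by_compartment(recs, ds.tes, ds.cmap)
    labels = ["exon", "intron", "upstream", "downstream", "intergenic"]
    for te_class in counts.copies.index:
        row = counts.copies.loc[te_class]
        assert row[labels].sum() == row["total"]
    assert int(counts.copies.loc["total", "total"]) == len(ds.tes)
    # bp conservation: every TE's bp fully attributed
    assert int(counts.bp.loc["total", "total"]) == sum(t.span.length for t in ds.tes)


def test_planted_genic_fraction_recovered_within_binomial_error():
    """delta chosen for a 20% gene-body placement rate -> observed share
    within 3 binomial standard errors of 0.20."""
    base = SyntheticSpec(seed=21, n_chroms=1, chrom_length=2_000_000, n_genes=200, n_tes=0)
    genes, chroms = generate_genome(base)
    clens = compartment_lengths(build_compartment_map(genes, chroms))
    g = clens.genic_bp() / clens.genome_total
    spec = SyntheticSpec(
        seed=21, n_chroms=1, chrom_length=2_000_000, n_genes=200, n_tes=4000,
        delta=0.2 / g,
    )
    ds = simulate_dataset(spec)
    recs = assign_all(ds.tes, ds.cmap)
    observed = sum(r.genic for r in recs) / len(ds.tes)
    se = np.sqrt(0.2 * 0.8 / len(ds.tes))
    assert abs(observed - 0.2) <= 3 * se


def test_flank_bp_monotone_in_flank_width(neutral_dataset):
    ds = neutral_dataset
    totals = []
    for flank in (500, 2000, 5000):
        clens = compartment_lengths(
            build_compartment_map(ds.genes, ds.chroms, flank_bp=flank)
        )
        totals.append(clens.by_label["upstream"] + clens.by_label["downstream"])
    assert totals == sorted(totals)


def test_family_counts_trivial_upstream(single_gene_cmap):
    recs = assign_all([_te("chr1", 3500, 3600)], single_gene_cmap)
    table = family_te_counts(recs, {"gA": {"FAM1"}})
    assert list(table.loc["FAM1"]) == [1, 0, 0]


def test_family_counts_gene_in_two_families_double_counts(single_gene_cmap):
    recs = assign_all([_te("chr1", 5500, 5600)], single_gene_cmap)
    table = family_te_counts(recs, {"gA": {"FAM1", "FAM2"}})
    assert list(table.loc["FAM1"]) == [0, 1, 0]
    assert list(table.loc["FAM2"]) == [0, 1, 0]


def test_family_planted_genic_excess_ordering():
    """Genes split into two families; family A holds the gene-dense half of
    the genic TEs, so its gene-region count must exceed family B's when the
    planted split is 3:1."""
    ds = simulate_dataset(
        SyntheticSpec(seed=33, n_chroms=1, chrom_length=500_000, n_genes=40, n_tes=3000)
    )
    recs = assign_all(ds.tes, ds.cmap)
    # plant the excess directly: family A owns 3x as many genes as family B
    gene_ids = sorted(g.gene_id for g in ds.genes)
    fam = {g: {"A"} for g in gene_ids[:30]}
    fam.update({g: {"B"} for g in gene_ids[30:]})
    table = family_te_counts(recs, fam)
    assert table.loc["A", "gene_region"] > table.loc["B", "gene_region"]
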