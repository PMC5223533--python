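"""synthetic_data: determinism, conservation, planted-bias recovery."""

import filecmp

import numpy as np
import pytest

from telandscape.core import ValidationError
from telandscape.compartments import build_compartment_map, compartment_lengths
from telandscape.assignment import assign_all
from telandscape.simulate import (
    SyntheticSpec,
    choose_expressed,
    generate_genome,
    generate_term_map,
    plant_te_landscape,
    simulate_dataset,
)
from telandscape.stats import go_enrichment


def test_emitted_files_are_byte_identical_under_fixed_seed(tmp_path):
    spec = SyntheticSpec(seed=5, n_chroms=1, chrom_length=400_000, n_genes=50, n_tes=500)
    simulate_dataset(spec, outdir=tmp_path / "a")
    simulate_dataset(spec, outdir=tmp_path / "b")
    for name in ("genes.gff3", "tes.out", "chrom_lengths.tsv", "expression.tsv",
                 "gene_terms.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


def test_no_genes_whole_genome_intergenic(tmp_path):
    spec = SyntheticSpec(seed=1, n_chroms=1, chrom_length=100_000, n_genes=0, n_tes=50)
    ds = simulate_dataset(spec, outdir=tmp_path)
    assert ds.genes == []
    clens = compartment_lengths(ds.cmap)
    assert clens.by_label["intergenic"] == 100_000
    assert (tmp_path / "genes.gff3").read_text() == "##gff-version 3\n"


def test_conservation_on_larger_genome():
    spec = SyntheticSpec(seed=6, n_chroms=3, chrom_length=1_200_000, n_genes=500, n_tes=0)
    genes, chroms = generate_genome(spec)
    assert len(genes) == 500
    spans = sorted((g.span.chrom, g.span.start, g.span.end) for g in genes)
    for (c1, s1, e1), (c2, s2, _) in zip(spans, spans[1:]):
        if c1 == c2:
            assert e1 <= s2  # non-overlapping by construction
    clens = compartment_lengths(build_compartment_map(genes, chroms))
    assert clens.genome_total == 3 * 1_200_000


def test_infeasible_gene_density_raises():
    spec = SyntheticSpec(seed=1, n_chroms=1, chrom_length=20_000, n_genes=50, n_tes=0)
    with pytest.raises(ValidationError, match="infeasible"):
        generate_genome(spec)


def test_delta_zero_places_no_genic_tes():
    ds = simulate_dataset(
        SyntheticSpec(seed=10, n_chroms=1, chrom_length=500_000, n_genes=50,
                      n_tes=1000, delta=0.0)
    )
    recs = assign_all(ds.tes, ds.cmap)
    assert sum(r.genic for r in recs) == 0
    assert ds.truth.genic_te_count == 0


def test_delta_one_realized_fraction_within_binomial_error():
    ds = simulate_dataset(
        SyntheticSpec(seed=12, n_chroms=1, chrom_length=800_000, n_genes=80, n_tes=4000)
    )
    p = ds.truth.expected_genic_probability
    observed = ds.truth.genic_te_count / ds.spec.n_tes
    se = np.sqrt(p * (1 - p) / ds.spec.n_tes)
    assert abs(observed - p) <= 3 * se


def test_delta_half_recovered_from_observed_over_expected():
    ds = simulate_dataset(
        SyntheticSpec(seed=13, n_chroms=2, chrom_length=2_000_000, n_genes=400,
                      n_tes=10_000, delta=0.5)
    )
    recs = assign_all(ds.tes, ds.cmap)
    clens = compartment_lengths(ds.cmap)
    g = clens.genic_bp() / clens.genome_total
    observed = sum(r.genic for r in recs) / len(ds.tes)
    assert abs(observed / g - 0.5) <= 0.1


def test_truth_record_consistent_with_emitted_files(tmp_path):
    from telandscape import io as tio

    spec = SyntheticSpec(seed=14, n_chroms=1, chrom_length=500_000, n_genes=60, n_tes=800)
    ds = simulate_dataset(spec, outdir=tmp_path)
    genes = tio.read_gff3_genes(ds.paths["genes_gff3"])
    chroms = tio.read_chrom_lengths(ds.paths["chrom_lengths"])
    tes = tio.read_repeatmasker_out(ds.paths["te_out"])
    cmap = build_compartment_map(genes, chroms, flank_bp=spec.flank_bp)
    recs = assign_all(tes, cmap)
    assert sum(r.genic for r in recs) == ds.truth.genic_te_count
    cat = ds.truth.category_counts
    assert sum(cat.values()) == spec.n_tes
    assert cat["exon_expr"] + cat["exon_non"] + cat["intron_expr"] + cat["intron_non"] \
        == ds.truth.genic_te_count


def test_te_class_mixture_and_length_ordering():
    ds = simulate_dataset(
        SyntheticSpec(seed=15, n_chroms=2, chrom_length=2_000_000, n_genes=400,
                      n_tes=3000)
    )
    by_class: dict[str, list[int]] = {}
    for te in ds.tes:
        by_class.setdefault(te.te_class, []).append(te.span.length)
    frac_dna = len(by_class["ClassII_DNA"]) / len(ds.tes)
    assert abs(frac_dna - 0.45) < 0.03
    # LTR fragments have the longest median, SINEs the shortest
    medians = {c: float(np.median(v)) for c, v in by_class.items()}
    assert medians["ClassI_LTR"] == max(medians.values())
    assert medians["ClassI_SINE"] == min(medians.values())


def test_planted_term_enriched_single_seed():
    ds = simulate_dataset(
        SyntheticSpec(seed=16, n_chroms=2, chrom_length=800_000, n_genes=160, n_tes=4000)
    )
    universe = {g.gene_id for g in ds.genes}
    rows = go_enrichment(ds.truth.genic_te_genes & universe, universe, ds.gene_to_terms)
    assert rows[0].term_id == ds.truth.planted_term


def test_unplanted_term_map_calibration_no_signal():
    """fold = 1: the 'planted' term is exchangeable with background terms, so
    its enrichment p is roughly uniform — check via mean over seeds."""
    base = SyntheticSpec(seed=20, n_chroms=1, chrom_length=600_000, n_genes=120,
                         n_tes=2000, planted_fold=1.0)
    ds = simulate_dataset(base)
    universe = {g.gene_id for g in ds.genes}
    study = ds.truth.genic_te_genes & universe
    ps = []
    for s in range(40):
        spec_s = SyntheticSpec(**{**base.__dict__, "seed": 100 + s})
        mapping, _ = generate_term_map(spec_s, sorted(universe), ds.truth.genic_te_genes)
        rows = go_enrichment(study, universe, mapping)
        (planted,) = [r for r in rows if r.term_id == base.planted_term]
        ps.append(planted.p_value)
    assert 0.25 <= float(np.mean(ps)) <= 0.75


def test_empty_term_universe_gives_empty_map():
    spec = SyntheticSpec(seed=1, n_background_terms=0, planted_fold=0.0)
    mapping, members = generate_term_map(spec, ["g1", "g2"], frozenset())
    assert mapping == {}
    assert members == frozenset()
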