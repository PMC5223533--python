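"""null_and_stats: closed-form oracles, enumeration oracles, MC consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telandscape.compartments import CompartmentLengths, compartment_lengths
from telandscape.core import ValidationError
from telandscape.simulate import SyntheticSpec, simulate_dataset
from telandscape.stats import (
    bh_adjust,
    chisq_goodness_of_fit,
    expected_genic_proportion,
    fisher_exact,
    fold_difference,
    go_enrichment,
    prop_test_given,
    prop_test_two_sample,
    randomize_te_placements,
)

import oracles


# -- analytic expectation and randomization null ----------------------------


def test_expected_genic_proportion_arithmetic():
    clens = CompartmentLengths(
        {"exon": 3000, "intron": 0, "upstream": 2000, "downstream": 2000, "intergenic": 13000},
        20000,
    )
    assert expected_genic_proportion(clens) == pytest.approx(0.15)
    full = CompartmentLengths({"exon": 500, "intron": 500}, 1000)
    assert expected_genic_proportion(full) == 1.0


def test_null_determinism_and_support(neutral_dataset):
    ds = neutral_dataset
    a = randomize_te_placements(ds.tes, ds.cmap, n_reps=50, seed=9)
    b = randomize_te_placements(ds.tes, ds.cmap, n_reps=50, seed=9)
    assert a.proportions == b.proportions
    assert all(0.0 <= p <= 1.0 for p in a.proportions)


def test_null_mean_matches_analytic_expectation(neutral_dataset):
    """Monte-Carlo mean within 3 standard errors of the genic bp fraction."""
    ds = neutral_dataset
    null = randomize_te_placements(ds.tes, ds.cmap, n_reps=2000, seed=3)
    se = null.std / np.sqrt(null.n_reps)
    assert abs(null.mean - null.analytic_expectation) <= 3 * se


def test_null_overlap_rule_exceeds_start_rule(neutral_dataset):
    """Any-overlap genic replicates sit above start-position replicates by a
    positive boundary term (a copy can overlap a gene it does not start in)."""
    ds = neutral_dataset
    start = randomize_te_placements(ds.tes, ds.cmap, n_reps=300, seed=3, rule="start")
    overlap = randomize_te_placements(ds.tes, ds.cmap, n_reps=300, seed=3, rule="overlap")
    assert overlap.mean > start.mean


def test_fully_genic_genome_always_proportion_one():
    spec = SyntheticSpec(seed=2, n_chroms=1, chrom_length=60_000, n_genes=4, n_tes=200)
    ds = simulate_dataset(spec)
    # restrict to a map where genes cover everything: synthesise directly
    from telandscape.compartments import CompartmentMap, Segment
    from telandscape.core import GenomicInterval

    length = 60_000
    cmap = CompartmentMap(
        {"chr1": length},
        {"chr1": [Segment(GenomicInterval("chr1", 0, length), "exon", ("g1",))]},
        flank_bp=0,
    )
    null = randomize_te_placements(ds.tes, cmap, n_reps=20, seed=0)
    assert set(null.proportions) == {1.0}


# -- proportion tests -------------------------------------------------------


def test_prop_test_given_exact_null_is_zero():
    res = prop_test_given(80, 400, 0.2, correction=False)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_prop_test_given_closed_form():
    # n (k/n - p0)^2 / (p0 (1 - p0)) computed by hand: 400*(0.1-0.2)^2/0.16
    res = prop_test_given(40, 400, 0.2, correction=False)
    assert res.statistic == pytest.approx(400 * 0.01 / 0.16)
    assert res.statistic == pytest.approx(25.0)


def test_prop_test_p_monotone_in_deviation():
    ps = [prop_test_given(k, 400, 0.2, correction=False).p_value for k in (80, 70, 60, 40)]
    assert ps == sorted(ps, reverse=True)


def test_prop_test_degenerate_p0_rejected():
    with pytest.raises(ValidationError):
        prop_test_given(1, 10, 0.0)
    with pytest.raises(ValidationError):
        prop_test_given(1, 10, 1.0)


def test_two_sample_identical_proportions_p_one():
    res = prop_test_two_sample(10, 100, 10, 100, correction=False)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_two_sample_matches_pooled_closed_form_and_contingency():
    from scipy.stats import chi2_contingency

    res = prop_test_two_sample(10, 100, 20, 100, correction=False)
    pooled = 30 / 200
    expect = (0.1) ** 2 / (pooled * (1 - pooled) * (1 / 100 + 1 / 100))
    assert res.statistic == pytest.approx(expect)
    chi2 = chi2_contingency([[10, 90], [20, 80]], correction=False)
    assert res.statistic == pytest.approx(chi2.statistic)
    assert res.p_value == pytest.approx(chi2.pvalue)

    res_c = prop_test_two_sample(10, 100, 20, 100, correction=True)
    chi2_c = chi2_contingency([[10, 90], [20, 80]], correction=True)
    assert res_c.statistic == pytest.approx(chi2_c.statistic)


def test_two_sample_empty_sample_rejected():
    with pytest.raises(ValidationError):
        prop_test_two_sample(0, 0, 1, 10)


def test_depletion_detected_with_planted_half_delta():
    """delta = 0.5 with >= 5000 copies: the one-sample test must reject hard."""
    ds = simulate_dataset(
        SyntheticSpec(seed=17, n_chroms=2, chrom_length=2_000_000, n_genes=400,
                      n_tes=5000, delta=0.5)
    )
    from telandscape.assignment import assign_all

    recs = assign_all(ds.tes, ds.cmap)
    k = sum(r.genic for r in recs)
    p0 = expected_genic_proportion(compartment_lengths(ds.cmap))
    res = prop_test_given(k, len(ds.tes), p0, correction=True)
    assert res.p_value < 0.001
    assert k / len(ds.tes) < p0


# -- chi-square goodness of fit and Fisher ----------------------------------


def test_chisq_equal_split_closed_form():
    obs = (758, 26162)
    total = sum(obs)
    expected = total / 2
    oracle = sum((o - expected) ** 2 / expected for o in obs)
    res = chisq_goodness_of_fit(obs, [0.5, 0.5])
    assert res.statistic == pytest.approx(oracle)
    assert res.df == 1


def test_chisq_zero_when_observed_equals_expected():
    assert chisq_goodness_of_fit([10, 10], [0.5, 0.5]).statistic == 0.0
    res = chisq_goodness_of_fit([30, 60, 10], [0.3, 0.6, 0.1])
    assert res.statistic == 0.0
    assert res.df == 2


def test_chisq_zero_expected_cell_rejected():
    with pytest.raises(ValidationError):
        chisq_goodness_of_fit([5, 5], [1.0, 0.0])


def test_fisher_small_table_enumeration_values():
    assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_degenerate():
    res = fisher_exact([[0, 0], [3, 4]])
    assert res.degenerate
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(4))
def test_fisher_matches_enumeration_oracle_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        t = [[int(rng.integers(0, 13)), int(rng.integers(0, 13))],
             [int(rng.integers(0, 13)), int(rng.integers(0, 13))]]
        res = fisher_exact(t)
        if res.degenerate:
            continue
        assert res.p_value == pytest.approx(oracles.fisher_two_sided(t), rel=1e-9)


def test_fold_difference_values():
    assert fold_difference(26162, 758) == pytest.approx(26162 / 758)
    assert fold_difference(5, 5) == 1.0
    assert fold_difference(0, 7) == 0.0
    with pytest.raises(ValidationError):
        fold_difference(3, 0)


# -- BH and enrichment ------------------------------------------------------


def test_bh_hand_computed_step_up():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.37]) == [0.37]
    assert bh_adjust([]) == []


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
def test_bh_matches_oracle_and_dominates_p(ps):
    qs = bh_adjust(ps)
    assert qs == pytest.approx(oracles.bh_step_up(ps))
    for p, q in zip(ps, qs):
        assert q >= p - 1e-12
        assert 0.0 <= q <= 1.0
    # order preservation: sorting by p sorts q
    order = sorted(range(len(ps)), key=lambda i: ps[i])
    assert [qs[i] for i in order] == sorted(qs)


def test_hypergeometric_enrichment_exact_value():
    # N=20, K=5 term genes, study n=5 with k=4 hits: p = 76/15504
    universe = {f"g{i}" for i in range(20)}
    term_genes = [f"g{i}" for i in range(5)]
    mapping = {g: {"T"} for g in term_genes}
    study = set(term_genes[:4]) | {"g10"}
    (row,) = go_enrichment(study, universe, mapping)
    assert row.study_hits == 4
    assert row.p_value == pytest.approx(76 / 15504)
    assert row.p_value == pytest.approx(oracles.hypergeom_upper_tail(4, 20, 5, 5))


def test_enrichment_zero_hits_p_one():
    universe = {f"g{i}" for i in range(10)}
    mapping = {"g9": {"T"}}
    (row,) = go_enrichment({"g0", "g1"}, universe, mapping)
    assert row.study_hits == 0
    assert row.p_value == 1.0
    assert row.q_value == 1.0


def test_enrichment_requires_study_subset_of_universe():
    with pytest.raises(ValidationError):
        go_enrichment({"x"}, {"a"}, {})
    with pytest.raises(ValidationError):
        go_enrichment(set(), set(), {})
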