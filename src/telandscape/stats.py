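"""Inferential machinery: randomization null for genic TE occupancy,
proportion tests, contingency statistics, BH correction and GO enrichment.

The randomization null keeps each TE's length and chromosome, draws a
uniform random start, and asks how many copies land with >= 1 bp inside a
gene body — the same genic rule the observed assignment uses.  The fast
analytic counterpart is the start-position expectation: the genic fraction
of the genome, (exon bp + intron bp) / genome bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import TECopy, ValidationError
from .compartments import CompartmentLengths, CompartmentMap


# ---------------------------------------------------------------------------
# Randomization null
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullDistribution:
    """Monte-Carlo genic-occupancy proportions under random placement."""

    proportions: tuple[float, ...]
    analytic_expectation: float
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.proportions) != self.n_reps:
            raise ValidationError("n_reps must equal the number of replicates")
        if any(not (0.0 <= p <= 1.0) for p in self.proportions):
            raise ValidationError("replicate proportions must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.proportions))

    @property
    def std(self) -> float:
        return float(np.std(self.proportions, ddof=1)) if self.n_reps > 1 else 0.0


def expected_genic_proportion(clens: CompartmentLengths) -> float:
    """Chance probability that a uniformly placed TE starts in a gene body."""
    if clens.genome_total <= 0:
        raise ValidationError("genome total length must be positive")
    return clens.genic_bp() / clens.genome_total


def randomize_te_placements(
    tes: Sequence[TECopy],
    cmap: CompartmentMap,
    n_reps: int = 1000,
    seed: int = 0,
    rule: str = "start",
) -> NullDistribution:
    """Length- and chromosome-preserving uniform random TE placement.

    Per replicate each TE receives a uniform start in ``[0, chrom_len)`` on
    its own chromosome, treated circularly (a copy running past the end
    wraps to the start) so every base is an equally likely start and the
    start-rule expectation is exactly the genic bp fraction; overlaps
    between placed copies are allowed.  A replicate's statistic is the
    genic fraction of copies under ``rule``:

    - ``"start"`` (default): a copy is genic iff its start base lies in a
      gene body.  The replicate mean matches the analytic start-position
      expectation (the genic bp fraction).
    - ``"overlap"``: the any-overlap reading (>= 1 bp inside a gene body,
      the assignment module's genic flag).  Its mean exceeds the start
      expectation by a boundary term that grows with copy length, which is
      why it is not the default comparator for the analytic expectation.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if rule not in ("start", "overlap"):
        raise ValidationError("rule must be 'start' or 'overlap'")
    if not tes:
        raise ValidationError("need at least one TE")
    per_chrom: dict[str, list[int]] = {}
    for te in tes:
        chrom = te.span.chrom
        if chrom not in cmap.chrom_lengths:
            raise ValidationError(f"TE {te.te_id} on unknown chromosome {chrom}")
        if te.span.length > cmap.chrom_lengths[chrom]:
            raise ValidationError(
                f"TE {te.te_id} is longer than chromosome {chrom}"
            )
        per_chrom.setdefault(chrom, []).append(te.span.length)

    prepared = []
    for chrom, lens in per_chrom.items():
        genic = cmap.genic_intervals(chrom)
        gstart = np.array([g[0] for g in genic], dtype=np.int64)
        gend = np.array([g[1] for g in genic], dtype=np.int64)
        lengths = np.asarray(lens, dtype=np.int64)
        prepared.append((gstart, gend, lengths, cmap.chrom_lengths[chrom]))

    rng = np.random.default_rng(seed)
    n_total = len(tes)
    props = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        genic_hits = 0
        for gstart, gend, lengths, chrom_len in prepared:
            starts = rng.integers(0, chrom_len, size=len(lengths))
            if len(gstart) == 0:
                continue
            hit = np.zeros(len(starts), dtype=bool)
            if rule == "start":
                idx = np.searchsorted(gstart, starts, side="right") - 1
                valid = idx >= 0
                hit[valid] = gend[idx[valid]] > starts[valid]
            else:
                # disjoint sorted genic runs: the run with the largest
                # start < end is the only candidate overlap
                ends = np.minimum(starts + lengths, chrom_len)
                idx = np.searchsorted(gstart, ends, side="left") - 1
                valid = idx >= 0
                hit[valid] = gend[idx[valid]] > starts[valid]
                wrap = starts + lengths - chrom_len  # circular tail length
                hit |= (wrap > 0) & (gstart[0] < wrap)
            genic_hits += int(hit.sum())
        props[rep] = genic_hits / n_total
    return NullDistribution(
        proportions=tuple(float(p) for p in props),
        analytic_expectation=expected_genic_proportion(
            _lengths_from_map(cmap)
        ),
        n_reps=n_reps,
        seed=seed,
    )


def _lengths_from_map(cmap: CompartmentMap) -> CompartmentLengths:
    from .compartments import compartment_lengths

    return compartment_lengths(cmap)


# ---------------------------------------------------------------------------
# Proportion tests ("test for equal or given proportions")
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropTestResult:
    statistic: float
    p_value: float
    observed: tuple[float, ...]
    null_value: Optional[float]
    df: int
    continuity_correction: bool


def prop_test_given(
    k: int, n: int, p0: float, correction: bool = False
) -> PropTestResult:
    """One-sample chi-square-form test of a proportion against ``p0``.

    Statistic (no correction): ``n * (k/n - p0)^2 / (p0 * (1 - p0))``; with
    Yates continuity correction |k - n p0| shrinks by 0.5 first.  p comes
    from the chi-square(1) survival function.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValidationError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValidationError("p0 must lie strictly inside (0, 1)")
    diff = abs(k - n * p0)
    if correction:
        diff = max(0.0, diff - 0.5)
    statistic = diff**2 / (n * p0 * (1.0 - p0))
    p = float(sps.chi2.sf(statistic, df=1))
    return PropTestResult(
        statistic=float(statistic),
        p_value=p,
        observed=(k / n,),
        null_value=p0,
        df=1,
        continuity_correction=correction,
    )


def prop_test_two_sample(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> PropTestResult:
    """Pooled two-sample proportion chi-square test (Yates by default)."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        # all successes or all failures: no evidence of a difference
        return PropTestResult(0.0, 1.0, (p1, p2), None, 1, correction)
    diff = abs(p1 - p2)
    if correction:
        diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
    statistic = diff**2 / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p = float(sps.chi2.sf(statistic, df=1))
    return PropTestResult(
        statistic=float(statistic),
        p_value=p,
        observed=(p1, p2),
        null_value=None,
        df=1,
        continuity_correction=correction,
    )


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    p_value: float
    df: int
    observed: tuple[int, ...]
    expected: tuple[float, ...]


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def chisq_goodness_of_fit(
    observed: Sequence[int], expected_probs: Sequence[float]
) -> ChiSqResult:
    """Multinomial goodness-of-fit chi-square against given cell probabilities."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValidationError("observed and expected_probs must be 1-D and aligned")
    if np.any(obs < 0):
        raise ValidationError("observed counts must be non-negative")
    if not np.isclose(probs.sum(), 1.0):
        raise ValidationError("expected_probs must sum to 1")
    expected = obs.sum() * probs
    if np.any(expected == 0):
        raise ValidationError("an expected count of 0 makes the statistic undefined")
    statistic, p = sps.chisquare(obs, f_exp=expected)
    return ChiSqResult(
        statistic=float(statistic),
        p_value=float(p),
        df=len(obs) - 1,
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in expected),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all same-margin tables
    at most as probable as the observed one.  A zero row or column margin is
    degenerate: p = 1 by convention, flagged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("need a 2x2 table of non-negative integers")
    degenerate = bool(np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0))
    if degenerate:
        return FisherResult(
            p_value=1.0,
            odds_ratio=float("nan"),
            table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
            degenerate=True,
        )
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return FisherResult(
        p_value=float(p),
        odds_ratio=float(odds),
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
    )


def fold_difference(count_a: int, count_b: int) -> float:
    """Ratio ``count_a / count_b``; undefined (error) for ``count_b = 0``."""
    if count_b < 1:
        raise ValidationError("fold difference undefined for a zero denominator")
    if count_a < 0:
        raise ValidationError("counts must be non-negative")
    return count_a / count_b


# ---------------------------------------------------------------------------
# Multiplicity and GO enrichment
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(q) for q in sps.false_discovery_control(ps, method="bh")]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    study_hits: int  # k: study genes carrying the term
    study_size: int  # n
    term_size: int  # K: universe genes carrying the term
    universe_size: int  # N
    p_value: float
    q_value: float


def go_enrichment(
    study_genes: set[str],
    universe_genes: set[str],
    gene_to_terms: Mapping[str, frozenset[str] | set[str] | Sequence[str]],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation test per term.

    For each term with >= 1 universe gene, p = P(X >= k) with X ~
    Hypergeom(N, K, n); q-values are BH-adjusted across all tested terms.
    Rows are returned sorted by (q, p, term_id).
    """
    if not universe_genes:
        raise ValidationError("universe must be non-empty")
    if not study_genes <= universe_genes:
        raise ValidationError("study genes must be a subset of the universe")
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe_genes:
        for term in gene_to_terms.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study_genes:
                term_study[term] = term_study.get(term, 0) + 1
    N, n = len(universe_genes), len(study_genes)
    terms = sorted(term_universe)
    pvals = []
    for term in terms:
        K = term_universe[term]
        k = term_study.get(term, 0)
        # survival function at k-1 gives P(X >= k); scipy works in log space
        pvals.append(float(min(1.0, sps.hypergeom.sf(k - 1, N, K, n))))
    qvals = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term_id=term,
            study_hits=term_study.get(term, 0),
            study_size=n,
            term_size=term_universe[term],
            universe_size=N,
            p_value=p,
            q_value=q,
        )
        for term, p, q in zip(terms, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return rows
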