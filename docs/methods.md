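# Methods

`telandscape` quantifies how transposable elements (TEs) are distributed
over the functional compartments of an annotated genome, and tests whether
gene bodies are depleted of TEs relative to chance — the comparative
pattern seen between cultivated rice species and their wild relatives,
where domesticated genomes carry markedly fewer TE copies inside genes
while flanking regions look alike.

## Compartment model

Each chromosome is partitioned exhaustively and disjointly into five
labels: **exon**, **intron**, **upstream** flank, **downstream** flank and
**intergenic**. A gene is its continuous exon–intron span (UTR-extended
spans are allowed); exons of all transcripts are union-merged, and a base
inside any overlapping gene is exonic if it is exonic in *any* of them,
otherwise intronic. Flanks extend a fixed `flank_bp` (default **2000 bp**,
the conventional promoter/terminator window) 5′ and 3′ of the span,
strand-aware, truncated at chromosome ends. Collisions resolve by the fixed
precedence exon > intron > upstream > downstream > intergenic; where one
gene's upstream flank meets another's downstream flank, upstream wins.
These tie-breaks are deterministic and configurable in the sense that the
partition builder is a pure function of (genes, chromosome lengths,
`flank_bp`); the precedence itself is a documented constant because the
downstream statistics require a true partition (compartment fractions must
sum to 1).

The implementation is an interval sweep (cut at every feature boundary,
classify each elementary slice, merge back); tests compare it base-by-base
against an independent per-base painting oracle on 100-kb chromosomes.

## TE assignment

One annotation record (one RepeatMasker `.out` row) is one TE copy; short
fragments are deliberately *not* rejoined, since fragment counts are what
the downstream copy-number statistics use. Each copy gets

* a **primary label** — the compartment with maximal base overlap, ties
  broken by the precedence above (stable for fragment-heavy annotations,
  unlike midpoint rules), and
* a **genic flag** — ≥ 1 bp overlapping exon or intron (the any-overlap
  "in the gene region" reading).

Copies are counted once (primary label) in occupancy tables so pies sum
to 1, but listed under every owner gene for gene-level queries; bp tallies
are split across labels by actual overlap. Repeat class strings map to the
five canonical classes (Class I LTR / LINE / SINE, Class II DNA, Other)
via an editable prefix table; simple repeats, satellites, low-complexity
runs and structural RNAs are dropped by default because they are not
transposable elements.

## Randomization null and depletion test

Chance expectation for gene-body occupancy uses two interchangeable
routes:

1. **Analytic start-position expectation** — the genic bp fraction
   `g = (exon + intron) / genome`.
2. **Monte-Carlo null** — per replicate every copy keeps its length and
   chromosome and receives a uniform random start over the whole
   chromosome, treated circularly (wrap-around), overlaps permitted.
   Circular placement makes every base an equally likely start, so the
   start-rule replicate mean equals `g` exactly; a bounded-start variant
   (`[0, L_chrom − L_TE]`) would inflate the hit rate by `O(L_TE/L_chrom)`
   and drift away from the analytic value as replicates accumulate.

The replicate statistic defaults to the start-position genic rule so that
it is directly comparable to the analytic expectation; the any-overlap
rule is available (`rule="overlap"`) and its mean exceeds the start rule
by a boundary term that grows with copy length — for fragment-heavy real
annotations that is the right comparator for the observed any-overlap
share, and both are reported by the pipeline.

The depletion test is the chi-square-form **test for equal or given
proportions**: one-sample against `g` (Yates continuity correction on by
default, matching the conventional behaviour of the R procedure of the
same name), two-sample pooled for cultivated-vs-wild contrasts. The
statistics are the closed forms; p-values come from the χ²(1) survival
function. Contingency analyses use the multinomial goodness-of-fit
chi-square, and Fisher's exact test (two-sided by probability-mass
ordering) whenever the table is 2×2; a zero margin returns p = 1 flagged
degenerate.

## Expression strata and enrichment

A gene is **expressed** when FPKM > 0 in *any* tissue (tissues are
pooled, as leaf/panicle/root RNA-seq is in the source analyses); genes
missing from the table default to non-expressed, with the count reported.
TEs whose primary label is exon or intron are cross-tabulated against
their owner genes' strata; a copy owned by genes in both strata counts
once per stratum and the duplication is itself reported, so conservation
is auditable.

Term enrichment is the upper-tail hypergeometric test
`p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)` per term (terms with no universe
gene are skipped), with Benjamini–Hochberg adjustment applied within each
tested family of terms — not globally across compartments — mirroring
per-region enrichment tables. No GO-DAG propagation is attempted: the
gene→term map is taken at face value.

## Density landscape

TE density tracks count a copy in a 100,000-bp window (the conventional
chromosome-painting resolution) iff its start lies in the window, so
non-overlapping windows conserve copy number exactly; the final partial
window is kept. K-means (k = 3, seeded k-means++ with 10 restarts, best
inertia) clusters windows by genic-TE count and relabels clusters
low/medium/high by ascending mean.

## Synthetic data

The generator emulates the statistical structure the analyses consume,
not sequence: multi-chromosome genomes (default 2 × 1 Mb); non-overlapping
genes at rice-like density (default 200 genes, one per 10 kb, giving a
genic fraction near 25%) with 1–8 exons and log-normal exon/intron lengths
(medians 200/400 bp); TE class mixture weighted toward DNA transposons by
copy count (45%) with LTR elements at 30%, and log-normal fragment lengths
at RepeatMasker-fragment scale (medians LTR 800, LINE 500, DNA/Other 250,
SINE 180 bp; overall mean ~500 bp, putting default TE coverage near 30% of
the genome); zero-inflated FPKM
(expressed genes drawn log-normal with per-tissue dropout); and a
gene→term map with one planted term.

Two planted biases drive the tests:

* **δ (depletion factor)** — a copy lands in a gene body with probability
  exactly `δ·g`; the remaining mass spreads over flanks and intergenic
  space in proportion to bp, and the copy is then placed uniformly among
  the starts that keep it inside a single segment of the chosen category.
  The genic indicator is therefore Bernoulli(`δ·g`) per copy, making the
  observed/expected genic ratio an unbiased estimator of δ: δ = 1 emulates
  wild genomes, δ = 0.5 cultivated ones. Gene placement uses an exact
  gap-partition construction (draw structures, verify total feasibility,
  split residual length multinomially into inter-gene gaps), so infeasible
  densities fail immediately rather than looping. A drawn TE length that
  fits no segment of its category is redrawn with the category held fixed,
  preserving the genic probability.
* **β (intron bias)** — inside expressed genes the intron placement rate
  is multiplied by β relative to exons; β = 10 produces the strong
  intron-over-exon excess seen in expressed genes, β = 1 is neutral.

What the generator does **not** model — sequence content, nested/clustered
insertions, insertion-age structure, overlapping genes (handled by
hand-built fixtures instead), expression-level correlation with TE
content beyond β — bounds what green tests show: they validate the
accounting, the null, the tests' calibration and the recovery of planted
effects, not the biology of any real genome.

The enrichment scenario used in the acceptance checks plants a 4-fold
term on a genome where roughly one third of genes carry gene-body TEs
(400 genes over 2 × 2 Mb, 1500 copies, δ = 0.5), the TE-bearing share
real expressed-gene sets exhibit; saturated genomes where nearly every
gene is TE-bearing would leave no contrast between study set and universe.

## Problem sizes and numerics

Default analysis sizes used by the test-suite and the acceptance script:
oracle equivalence on 20 × 100-kb chromosomes (300 copies each); null
calibration over 200 simulated neutral genomes (800 kb, 80 genes, 800
copies each) testing at α = 0.05; δ-recovery on one 2-Mb genome with
10,000 copies; exhaustive Fisher verification over all 2×2 tables with
margins ≤ 12; 100 seeded term maps for the planted-enrichment ranking.
Hypergeometric tails and χ² survival functions are evaluated by scipy in
log space; Fisher enumeration in the oracles uses exact rational
arithmetic. All randomness flows through seeded `numpy` generators, with
each synthetic stage on its own spawned stream, so every emitted file and
report is byte-reproducible under a fixed seed.

## Known limitations

* The depletion test compares the observed any-overlap genic share with
  the start-position expectation; the two coincide under the generator
  (copies sit inside single compartments) but diverge for fragment-heavy
  real annotations, where the Monte-Carlo overlap null is the appropriate
  expected value — both are reported.
* Nested or overlapping repeat hits are all counted (no deduplication);
  copy counts from heavily fragmented annotations overweight old elements.
* BH control is per term family; no across-family error control.
* The pipeline consumes an FPKM table and annotation files as given; it
  performs no quantification, masking or ortholog inference.
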