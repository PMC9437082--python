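# Methods

This note records the models, parameter choices and numerical conventions
behind `magcat`, and what the synthetic-data tests do and do not establish.

## Quality scoring and admission

Completeness and contamination are *inputs*: marker-gene estimation,
chimerism detection and rRNA/tRNA discovery are upstream tools whose outputs
arrive as a TSV. The quality score is QS = completeness − 5 × contamination
(percent scale; may be negative) and admission requires completeness > 50,
contamination < 5, QS > 50 and a passing chimerism flag — all inequalities
strict, read directly from the rule they encode. Because the QS filter and
the chimerism gate are independent row predicates, their order of
application cannot change the admitted set (they commute).

Tiers are evaluated high → near-complete → medium → fail, so they are
mutually exclusive. The catalog's "medium" bound (< 5% contamination) is
stricter than the community MIMAG standard's < 10%; the looser bound is
available as `assign_tier(..., mimag_medium=True)`. The tRNA criterion
counts distinct amino-acid types (≤ 20), not tRNA gene copies.

Age binning tiles days 0–1162 into the nine month-labels 0, 1, 3, 6, 12,
18, 24, 30, 36. The printed source ranges overlap at day 900 ("721–900" and
"900–1162"); we assign day 900 to the 30-month bin (the lower bin's
inclusive upper bound wins) so the bins tile without gaps.

## k-mer distances

Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
complement; windows containing N are dropped. Defaults k = 21, s = 1000
match the sketching tool commonly used for genome distances. Hashing is the
splitmix64 finalizer over a 2-bit packed k-mer code XORed with the seed —
fixed, published, and vectorizable, so sketches are bit-reproducible across
runs and platforms (the commonly used MurmurHash/xxHash libraries are not
part of this package's dependency footprint).

The Jaccard estimate uses the merged bottom-s estimator (shared hashes among
the s smallest of the union). Distance follows the standard Poisson k-mer
survival model d = −(1/k)·ln(2j/(1+j)), clipped to [0, 1] with j = 0 → d = 1
(a clip, not infinity). ANI = (1 − d) × 100. The alignment fraction is
approximated by k-mer containment |A∩B|/|A| with the "larger" convention
(max over the two orientations); this is alignment-free and oracle-testable
while preserving the ≥ 0.30 gating semantics of alignment-based AF. For the
genome sizes this package targets in tests, containments are computed on the
exact canonical k-mer sets; sketch-based approximations engage only above a
configurable set-size threshold. One k-mer framework serves both the
clustering threshold and within-SGB distances; alignment-based ANI tools
would differ in the second decimal, which is within the tolerance of every
statistic computed downstream.

## Species clustering

Genomes are processed in descending representative score
(QS + 0.5 × log₁₀(N50), N50 in bases); ties break by higher completeness,
then larger N50, then lexicographic id. A genome joins the *best*
(highest-ANI) qualifying representative — mirroring centroid-style
dereplication — rather than the first found; `assign="first"` restores the
other convention. The primary pre-grouping skips representative comparisons
at Mash distance > 0.10; `exhaustive=True` disables it for oracle tests.
Chunked mode shuffles genomes with a recorded seed, dereplicates each chunk,
re-dereplicates the chunk representatives, and lets members inherit their
round-1 representative's final cluster; representatives are re-scored
globally in the final round. Isolate genomes are promoted to representative
after clustering (membership never changes).

## Subspecies

Within-SGB distance matrices are cut with complete linkage at heights 0.03
(97% ANI) and 0.01 (99% ANI), the conversion being ANI = (1 − d) × 100.
The cut is inclusive (join while merge height ≤ cutoff) — the source is
silent on inclusivity, and the inclusive reading preserves the guarantee
that the maximum intra-subcluster distance never exceeds the cutoff.
scipy's agglomerative implementation stands behind the cut; a brute-force
agglomeration oracle checks it for n ≤ 8.

## Strain heterogeneity

Bases with PHRED quality < 30 are removed *before* the ≥ 10× depth test (the
order matters for columns that pass only with low-quality bases; the cited
workflow filters bases first). A considered position is polymorphic iff its
dominant allele frequency is ≤ 0.80 (strictly > 0.80 is non-polymorphic), so
a 50/50 tie is polymorphic deterministically. Indels and non-ACGT calls are
ignored. In nonsynonymous mode, the denominator shrinks to positions inside
annotated CDS features and the minor (second-most-frequent) allele is
substituted into the reference codon at its position — other codon positions
keep the reference base — and translated with bacterial table 11; stop
changes count as nonsynonymous. Whether the study's denominator was
all considered positions or coding positions only is not stated; both modes
are provided (`nonsynonymous_only`).

## Phylogenetic diversity

Faith's PD of a leaf subset is the branch-length sum over the union of
root-to-leaf paths, root-inclusive by default (matching the common `pd`
implementation's include-root behavior); a root-exclusive toggle exists
since the convention is not stated. Under the root-inclusive definition,
pruning the tree before summing and summing induced edges on the full tree
are equivalent, so the question of which the original analysis did does not
affect the result. Gain% = 100 × (PD_all − PD_subset)/PD_subset, undefined
(error) for an empty subset. Zero-length branches and polytomies are
allowed.

## Pan-genome statistics

Core genes have prevalence ≥ 0.90 (inclusive — "at least 90%"); differential
prevalence uses strict > 0.70 / < 0.30 — both boundaries read from their
defining phrasings. PERMANOVA decomposes squared distances
(SS_total = Σ_{i<j} d²/n; within-group analogue per group), with pseudo-F,
R² = SS_among/SS_total, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under
free label permutation (genomes with missing metadata are expected to be
pre-filtered, matching the original exclusion rule). The implementation is
in-package because R² is part of the contract; an established library's
PERMANOVA serves as the independent oracle in the tests.

Protein clustering is greedy and incremental at 95% identity: longest
sequence first, identity = identical residues over the shorter sequence's
length, joining the best-matching representative (the `-g 1` semantics of
the cited tool). Alignments are local Smith–Waterman with BLOSUM62 and
affine gaps 11/1 (standard defaults; the source is silent). The homolog
scan against a reference gene cluster qualifies a hit at identity ≥ 70%
over the alignment *and* query coverage ≥ 50%; the coverage gate replaces
the original e-value < 1e-10 criterion because a pairwise aligner has no
database-size-dependent e-value model — both thresholds are configurable.
At most one qualifying hit counts per query.

## Synthetic data: the stated world

* **Conspecific genomes** evolve from one random root by iid per-site
  substitution, uniform over the three alternative bases, no indels and no
  transition/transversion bias. The per-genome rate r solves
  1 − 2r + (4/3)r² = target pairwise identity, so *pairwise* ANI (not
  root-to-leaf identity) hits the target; positional comparison is then an
  exact alignment, which is what makes the generator an oracle. Contig
  lengths are log-normal with median 50 kb so N50 statistics are nontrivial.
* **Degraded bins** drop shuffled contigs until the kept base fraction
  reaches the completeness target and append foreign-species contigs for
  contamination — realized values are within one contig of target and are
  recorded as truth.
* **Pileups** draw depth Poisson (or negative-binomial when overdispersed),
  plant a minor allele at a frequency uniform in (0.30, 0.50) at a
  `polymorphic_fraction` of sites, and add sequencing errors at the
  quality-implied rate. The minor-allele range is chosen once as a
  detectable strain-mixture regime: at depth ~100 the probability that a
  planted site's sampled minor frequency falls below the 0.20 detection
  margin is < 2%, so parameter recovery is limited by binomial counting
  noise, not by the generator.
* **Presence matrices** stratify genomes into two equal groups, draw
  accessory prevalences uniformly, set core prevalence to 1, and plant
  differential genes at specified per-group prevalences; all-zero columns
  are dropped. The quality-table generator allocates tier counts exactly
  (stratified, shuffled) so configured fractions hold by construction for
  every seed.
* **Trees** are random binary joins with exponential branch lengths
  (mean 0.1), root included.

A green synthetic test therefore establishes that the estimators recover
the parameters of this idealized world at the stated tolerances. It does
not establish robustness to indels, repeat content, uneven coverage,
assembly chimerism, codon bias, or phylogenetically structured gene gain
and loss — none of which the generators emulate.

## Numerical conventions and degenerate inputs

* N50 returns a member of the input; empty contig lists are errors.
* Empty canonical k-mer sets (genome shorter than k) are errors for
  distance estimation; sequences shorter than k give an empty k-mer set.
* Jaccard of two empty sets, PD of an empty leaf subset, PERMANOVA with a
  group of size 1, similarity of two empty SGB sets: all errors rather than
  silent defaults. A sample with an empty SGB set in exactly *one* study
  yields NA similarity and is excluded from medians.
* All randomized procedures (sketch seeds, chunk shuffles, permutation
  tests, every generator) take explicit integer seeds and are bit-stable
  given them.

## Known limitations

ANI here is k-mer-based, not alignment-based; AF is containment, not an
aligned fraction. Greedy dereplication is order-dependent by design (score
order makes it deterministic). The pileup TSV dialect stores one mean
quality per column, so the base-quality filter is all-or-nothing per column
in that dialect (the mpileup reader filters per base). PERMANOVA supports
one factor without strata. Protein alignment is O(nm) per pair and meant
for the package's test-scale inputs, not millions of proteins.
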