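# Methods

`hetmir` analyses non-additive miRNA expression in reciprocal-cross hybrid
laying hens against their purebred parents, and relates it to heterosis in
egg-laying traits. This note describes the statistical model, the tunable
parameters, what the synthetic-data generators do and do not emulate, the
numerical choices, and the known limitations.

## Study design and data model

The design is two purebred parental lines (roles `P1`, `P2`) and their two
reciprocal hybrids (`H12`, `H21`), with four replicate small-RNA libraries
per genotype (16 libraries). Line names are mapped to roles in the pipeline
config (by default `R→P1`, `W→P2`, `RW→H12`, `WR→H21`), so the code is not
hardwired to any particular cross.

Counts are integer miRNA × sample matrices. Normalization is counts per
million (CPM): `count / library_total × 1e6`. miRNAs below **10 CPM in
every library** are removed before testing; the comparison is strict, so a
miRNA at exactly 10 CPM anywhere is kept.

## Read quantification

Reads are 3′-adapter trimmed: the leftmost position where the read
continues as an exact prefix of the adapter (at least `min_adapter_overlap`
= 6 nt) is found, and everything from that position on is removed, quality
in lockstep. Reads are kept when the trimmed length is 18–30 nt and the
mean base quality is strictly above Phred 20. Per-base quality trimming is
not attempted. An optional 5′ trim applies the mirrored rule and is off by
default, since standard small-RNA library preparations leave only a 3′
adapter in the read.

Clean reads are assigned to mature miRNA sequences (FASTA, U normalized to
T): exact sequence identity first; only a read with no exact match is
considered at Hamming distance 1 with equal length (no indels). A read
matching several mature ids increments **all** of them — mature catalogues
contain distinct ids with identical sequences (e.g. let-7 family members),
and per-id counting is the convention that keeps such ids exchangeable —
while the assigned-read statistic counts the read once, so
`passed = assigned + unassigned` holds.

## Differential expression

The DE model is a conditional exact binomial test on pooled counts. Within
each contrast group the counts and library totals are pooled; under the
null of equal relative abundance, the group-1 count conditioned on the
two-group total is

    k1 | (k1 + k2)  ~  Binomial(k1 + k2, n1 / (n1 + n2)),

and the two-sided p-value follows the minimum-likelihood rule: sum the
probabilities of all outcomes no more likely than the observed one. q is
Benjamini–Hochberg across the miRNAs of the contrast. A miRNA is called
differentially expressed when **q < 0.05 and |log2 fold change| ≥ 1**,
conjunctively; the fold change is computed on the CPM scale with a
pseudocount of 0.5 added to both groups (counts as low as 1 occur, and the
pseudocount keeps log ratios finite without dominating moderate counts).

Replicate-level biological variability is deliberately *not* modelled —
the test sees pooled counts, so its p-values are anti-conservative with
respect to replicate noise. The fold-change gate is what keeps the
realized false-call rate low (see "Limitations").

The mid-parent profile A is synthesized per pseudo-replicate as
`A_i = (P1_i + P2_i) / 2` on the CPM scale, pairing parental replicates by
index. For hybrid-vs-A contrasts the A profiles are converted back to
pseudo-counts at the rounded mean parental library size, so the same
pooled binomial machinery applies.

## Inheritance-mode classification

For each miRNA and each hybrid H, four contrast statuses feed the call
(H vs P1, H vs P2, P1 vs P2, H vs A), each `up`/`down`/`ns`. The decision
order tests transgressive patterns — the strictly stronger statements —
first:

1. **over-dominant**: H up vs both parents;
2. **under-dominant**: H down vs both parents;
3. **high-parent dominant**: H up vs exactly one parent, ns vs the other;
4. **low-parent dominant**: H down vs exactly one parent, ns vs the other;
5. **additive**: parents differ (P1 vs P2 significant) and H ≈ A;
6. **ambiguous**: H up vs one parent and down vs the other (a pattern the
   standard taxonomy does not name; it is reported separately rather than
   forced into a category);
7. **conserved**: anything else. In particular, a hybrid that differs from
   A with no other signal names no category and is reported conserved.

This order maps each of the 3⁴ possible status combinations to exactly one
mode, and is invariant under relabelling the parents. Per-miRNA calls in
the two hybrids are merged: `in_both` when the same non-conserved mode
holds in both, `in_H12`/`in_H21` when only one hybrid carries a
non-conserved mode, `none` otherwise. Category summaries count unique
miRNAs; a miRNA with two *different* non-conserved modes across hybrids
contributes to both categories, so the counts partition the DE set exactly
when per-miRNA modes agree across hybrids.

## Phenotypes and heterosis

A lay record is a binary vector over days. A clutch is a maximal run of
consecutive laying days — standard poultry usage; per hen the mean run
length is the clutch-size summary (the maximum is reported alongside).
The sum of clutch lengths equals the egg number by construction.
Mid-parent heterosis in percent is

    H% = 100 × (F1 − MPV) / MPV,   MPV = (P1 + P2) / 2,

symmetric in the parents and invariant to rescaling all three means.
Group comparison is descriptive (mean/SD/n); inferential machinery such as
ANOVA with post-hoc tests is ordinary off-the-shelf statistics and out of
scope here.

## Targets, enrichment, network

Predicted targets carry an opaque real-valued aggregate score; rows are
kept when the score is ≥ 50 (inclusive) and the gene is in the expressed
mRNA set. Over-representation of gene sets in the filtered target list
uses the one-sided upper-tail hypergeometric test (`P(X ≥ k)` for a
background of N genes, K set members, query of n) with BH control at
q < 0.05; depletion is not tested. The regulatory network keeps a
candidate (miRNA, gene) pair as an edge when the Pearson correlation of
miRNA CPM against mRNA expression across all shared samples is **≤ −0.9,
inclusive**. Candidate pairs are restricted to the filtered target table
(configurable). Exports are a SIF edge list, a node-attribute table
(node type, and the merged inheritance mode for miRNAs, `unclassified`
when absent from the mode table) and GraphML.

## Synthetic data generators

The generators exist so every stage is testable against planted truth.

**Counts.** Negative-binomial draws with variance μ + φμ²; φ defaults to
0.1, a typical replicate-level variability for small-RNA libraries.
Genotype mean CPMs implement the planted mode exactly: conserved — all
four genotypes equal; additive — parents separated `effect`-fold, hybrids
at the arithmetic mid-parent; hp/lp dominant — hybrid at the high/low
parent; over/under-dominant — parents equal, hybrid `effect`-fold
above/below them. A planted non-additive mode may target one hybrid or
both; the out-of-scope hybrid sits at mid-parent (truly additive there)
when the parents differ, or at the shared parental level (truly conserved)
when they do not. Planted baselines are log-uniform in 20–500 CPM —
moderately expressed, as differential miRNAs tend to be — while a
heavy-tailed lognormal background carries the bulk of the library mass, so
planted fold changes perturb library composition only marginally.
Per-library totals jitter uniformly within ±10% of the nominal library
size, which makes CPM normalization non-trivial. Expected count =
mean CPM × library total / 1e6. The truth table records the exact planted
mean matrix, so planted-mean correctness is testable without sampling
error.

**Lay records.** A two-state Markov chain per hen: `p_lay` is the
probability of laying after a pause day, `persistence` the probability of
continuing a clutch. Day 0 starts from the stationary distribution, so the
expected egg number is the closed-form stationary rate
`p / (p + 1 − q)` times the number of days — the oracle the simulation
tests converge against. It is the simplest generator with a tunable
clutch-length distribution.

**mRNA profiles.** Planted genes are affine-decreasing functions of their
miRNA's CPM profile plus Gaussian noise; the slope is calibrated per pair
(`b = σ / (sd_m · sqrt(1/r² − 1))`) so the expected Pearson correlation
equals the requested target. With zero noise the realized correlation is
−1 exactly regardless of the target. Background genes are independent
lognormal profiles; the accompanying target table scores planted pairs in
[50, 100] and decoys below 50.

**Reads.** Each read is its mature sequence, with exactly one random
substitution at the chosen error rate, followed by the 3′ adapter, at
uniform Phred 40. Mature sets generated for round-trip testing are
rejection-sampled to pairwise Hamming distance ≥ 5 so single-substitution
reads cannot cross over between miRNAs.

What the generators do **not** emulate: isomiRs and length heterogeneity,
rRNA/tRNA contamination, GC- or sequence-dependent biases, correlated
replicate structure (batch effects), mRNA count noise (profiles are
continuous), and genotype-specific mRNA regulation beyond the planted
anti-correlations. Passing tests therefore demonstrate correctness of the
pipeline's logic under its stated model, not robustness to every artefact
of real libraries.

## Numerical choices

- Exact test, small totals (k1+k2 ≤ 2000): direct vectorized enumeration
  of the conditional pmf. Larger totals: the binomial pmf is unimodal, so
  the observed tail is a single cdf/sf call and the opposite tail's
  boundary is located by binary search along the monotone flank — exact to
  floating precision at any total, and agreeing with enumeration to
  ~1e-12 at the branch crossover.
- Probability ties in the minimum-likelihood rule use a relative slack of
  1e-7, so exact ties (e.g. the symmetric p₀ = 1/2 case) survive
  floating-point noise. p is floored at the smallest positive double and
  k1 + k2 = 0 returns p = 1 by convention.
- BH uses a stable sort, so tied p-values keep input order; q is clipped
  to [0, 1] with monotone enforcement from the largest p down.
- Mid-parent pseudo-counts are rounded to integers at the rounded mean
  parental library size; at 1M-read depth the rounding error is below
  1 CPM-equivalent.
- Constant expression vectors have no defined correlation; such candidate
  pairs are skipped with a warning rather than treated as edges.
- A genotype with a single hen reports SD = 0 with a `single_hen` flag
  rather than NaN, and is logged.

## Limitations

- **Pooled binomial vs replicate noise.** The binomial test conditions on
  pooled counts and is anti-conservative under biological overdispersion;
  at 4M pooled reads it flags relative differences of a few percent as
  significant. The conjunctive 2-fold gate is what controls realized
  false calls (measured ≤ 4% of truly conserved miRNAs at φ = 0.1). A
  negative-binomial GLM would model the dispersion but is a different
  method from the one implemented here.
- **Additive vs high-parent dominance are confusable at large parental
  effects.** The arithmetic mid-parent satisfies `mid/high = (1+e)/(2e)`,
  which is strictly above 1/2 for every effect size e — so the expected
  |log2 ratio| of the hybrid-vs-high-parent contrast is always below the
  2-fold gate, and a truly additive hybrid shows the status pattern
  (up vs low parent, ns vs high parent) in expectation. The
  dominance-first decision order then calls it high-parent dominant;
  additive plants at effect 8 are recovered only ~20–45% of the time
  (when sampling noise pushes the realized fold past the gate), while the
  four dominant/transgressive categories recover at 98–100%. Reordering
  additive before dominance mirrors the failure onto truly hp/lp-dominant
  miRNAs, whose hybrid-vs-A ratio is equally inside the gate, and judging
  "similar to A" by q alone collapses under the pooled test's
  anti-conservativeness. This is an intrinsic identifiability limit of
  the threshold taxonomy, not an implementation defect; additive calls
  are most reliable when the parental difference is modest (below ~3-fold,
  where the mid-parent hybrid is within the gate of *both* parents).
- Reference problem sizes: 200 miRNAs with 16 one-million-read libraries
  for recovery studies, 60–150 hens over 200 days for phenotype studies,
  40 miRNAs × 130 genes for network recovery. These are the package's
  default study dimensions for its own validation suites.
- Genome alignment, annotation against miRNA/ncRNA databases, novel-miRNA
  prediction and seed-match target prediction are upstream tools' jobs;
  this package consumes their outputs.
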