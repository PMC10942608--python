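# Methods

This note documents the statistical model behind `allelospec`, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Measurement model

The unit of observation is a pair of allelic read counts (human-allele,
chimpanzee-allele) per feature (gene or ATAC peak) per sample, produced
twice: once with reads aligned to the human reference and once to the
chimpanzee reference. Given a feature's total allelic count *N*, the
human count is modeled as Binomial(*N*, *p*) with
*p* = 2^L / (1 + 2^L), where *L* = log2(human/chimp) is the
cis-regulatory fold-change. Everything downstream follows the sign
convention **positive L = human-biased**.

### QC and normalization

- **Chromosome exclusion.** Features on excluded chromosomes (default
  chr20, which is aneuploid in the hybrid lines this design targets)
  are removed before any statistics.
- **Contamination correction.** A fraction *f* of pure chimpanzee cells
  inflates chimpanzee-allele counts by a factor 1 + 2f/(1−f) globally.
  Per sample we compute r = Σhuman / Σchimp over autosomal included
  features (sex chromosomes are left out of the ratio but their
  features are kept — the expected balance argument is cleanest for
  autosomes) and multiply every chimpanzee count by r, which forces the
  global log2 ratio to exactly 0 and implies the estimate
  f̂ = (1/r − 1)/(1/r + 1), clipped to [0, 1). The correction is
  applied to every sample, is idempotent, and is implemented as
  continuous scaling rather than integer read subtraction: equivalent
  in expectation, deterministic, and proportion-preserving. Counts are
  real-valued afterwards; operations that need integers round half away
  from zero and log it.
- **Dual-reference filters.** A feature whose fold-change differs by
  more than 1 log2 unit between the two reference-genome runs is
  treated as mapping-biased and dropped. For ATAC, an additional
  replicate-resolved rule drops peaks whose two reference runs disagree
  in sign with |difference| > 1 in any replicate; zero fold-changes are
  sign-compatible with both signs.

A known property of global-ratio normalization: when expression is
heavy-tailed and a minority of features carry real divergence, the few
largest features move r by a few percent, imprinting a small
(|L| ≲ 0.1–0.3) systematic shift on all other features. At very high
per-feature counts this shift is statistically detectable, so the
allelic test's calibration guarantee is stated (and verified) under the
all-null condition; in mixture conditions the package's verified
guarantees are sensitivity ≥ 0.9 for |L| ≥ 1 and precision ≥ 0.95 among
significant calls with estimated |L| ≥ 0.5. Consumers who need
small-effect calls should treat |L| < 0.3 calls with caution — this is
a property of the normalization scheme, not of the test.

### Allelic-imbalance test

Normalized allelic counts are summed by species across all samples of a
cell type (lines and replicates pooled) and tested with the exact
two-sided binomial test at p0 = 0.5, using equal-tail doubling:
p = min(1, 2·min(P(X ≤ k), P(X ≥ k))). FDR is Benjamini–Hochberg
within each (cell type × reference) family, step-up with monotone
enforcement and no π0 estimation (deterministic and conservative).
Significance requires FDR < α (default 0.05) under **both** references
plus all applicable filters: dual-reference concordance for all
features; for ATAC additionally the mean-count rule (mean across a cell
type's replicates ≥ 25 reads from either allele, evaluated per cell
type under both references) and the replicate sign-discordance rule
(|L| > 1 in one replicate contradicted by an opposite-sign replicate;
cell types with a single replicate are exempt).

The binomial test deliberately replaces a negative-binomial GLM with a
line covariate: with counts pooled within cell type, the exact test is
correctly calibrated under the generative model (the binomial split is
exact conditional on totals), and the replicate- and dual-reference
consistency filters absorb line-level artifacts. Overdispersion
modeling is a possible extension; it would widen, not shift, calls.

The reported fold-change is log2((h + 1)/(c + 1)) with pseudocount 1
(no shrinkage), matching the convention used for browser-track ratio
computation.

### Cell-type specificity

- *Narrow genes*: TPM < 1 in every cell type except one, and above a
  `high` threshold (1–5) in that one. Monotone in `high`.
- *Broad genes*: Welch's t-test on log2(CPM+1) of total counts for
  every cell-type pair; a gene is specific to c iff every pair (c, c′)
  has FDR < α under both references. Zero-variance genes get p = 1 (not
  NaN) to keep BH denominators stable. The test is Welch rather than a
  count GLM for the same self-containment reason as above; at the
  replicate counts and effect sizes the generator produces, it has the
  required power.
- *Peaks*: narrow = called as a peak in exactly one cell type on
  depth-matched (exact multivariate-hypergeometric down-sampled) data;
  broad = pooled-CPM |log2 ratio| (pseudocount 1) above a threshold
  (0.5 or 1.0) against every other cell type. A consistent direction
  across pairs is not required. If two cell types both pass in absolute
  terms (one uniquely high and one uniquely low), the call is ambiguous
  and left empty rather than arbitrarily assigned.

### Enrichment

2×2 tables of (specific × imbalanced) use the sample odds ratio
ad/bc with Wald 95% CI exp(ln OR ± 1.96·se), se = √(1/a+1/b+1/c+1/d),
and a normal-approximation p. One zero cell triggers the
Haldane–Anscombe +0.5 correction (flagged); two zero cells in a line
leave the OR undefined (NaN, flagged) rather than infinite.
Stratification uses equal-size (not equal-width) bins of the ascending
covariate, ties broken by feature id, remainder features assigned to
the last bins — fully deterministic. The split-replicate control
computes specificity on one sample half (default: hybrid line 1) and
imbalance on the other, breaking the shared-noise circularity that can
inflate the full-data OR.

### Lineage-selection test

Constraint on a gene's cis-regulation is proxied by the variance of its
allelic ratio ref/(ref+alt) across many individuals of one species,
after excluding individuals with fewer than 10 reads from either allele
(so 11 ref / 2 alt is excluded); n−1 variance, undefined below 2
usable individuals. Per gene, the deviations |ratio − 0.5| implied by
the hybrid's per-replicate interspecies fold-changes are compared with
the population deviations by a Mann–Whitney U test — exact tie-aware
permutation enumeration when C(n1+n2, n1) ≤ 20,000 arrangements,
otherwise normal approximation with tie and continuity corrections.
The two-sided exact p counts arrangements with |U − n1n2/2| at least
as extreme as observed. The ranking score is −log10(p) signed by the
interspecies direction (+ = human-biased). Note the test is two-sided:
a gene with unusually *small* interspecies divergence relative to its
population spread also scores high in magnitude; in the power analyses
this only adds sign-symmetric noise to the null background.

Per gene set, two tests must both pass for a selection call:

1. **Directional binomial** — exact two-sided binomial on the count of
   human-biased members at p0 = 0.5, BH across sets, FDR < 0.05.
2. **Preranked enrichment** — weighted Kolmogorov–Smirnov running sum
   on the signed ranking (increments |score|^1 in-set, uniform
   decrements out-of-set; ES = maximum signed deviation, ties to the
   first occurrence). The null is 1000 random same-size gene sets
   (gene-label permutation — only ranks exist in preranked mode), with
   perm_p = (1 + #{|ES_null| ≥ |ES|})/(1 + n_perm), so perm_p ≥
   1/(1+n_perm) by construction; BH across sets, FDR < 0.25.

### dEE / dCAE

For a feature's fold-change vector over the cell-type panel with
target entry t: entries with sign opposite to t are set to 0 and
dEE = |t| / Σ|zeroed entries| ∈ [0, 1]. By convention dEE(t = 0) = 0 —
a zero effect is maximally non-specific (the raw formula would be 0/x
or 0/0 there). The metric is invariant to positive rescaling and to a
global sign flip, and is panel-dependent by construction, so
integrative RNA/ATAC analyses run on the 5-cell-type panel shared by
both assays (the RNA-only cell type is dropped). A feature is
cell-type-specifically imbalanced in c iff it is significant in c and
dEE_c ≥ 0.75. The concordance test then counts, among peak–gene pairs
(peak assigned to the nearest strand-aware TSS from the peak midpoint;
ties by lower gene start, then gene id) jointly specific in the same
cell type, how many share the fold-change direction, against the exact
binomial null of one half.

### Chromatin states

Peaks are labeled with one of 15 universal chromatin states by largest
overlap (ties resolved by fixed vocabulary order and logged; an
any-overlap mode duplicates peaks into all touched states). Divergence
per state is the median |L| per (state, cell type), z-scored across
states within the cell type; z-scoring the per-peak values first and
taking per-state medians is available behind a flag, as the two
orderings of "median" and "z-score" are both defensible summaries
(the default is the across-state z-score of medians). ASCA–ASE
coupling is the Pearson correlation (p from the t transform, n−2 df)
between peak and nearest-gene fold-changes per (state, cell type),
reported only for cells with ≥ 15 peaks, with subsets: all peaks,
nominally imbalanced peaks (binomial p < 0.05), promoter states
excluded, and TSS-proximal (< 30 kb) vs distal (≥ 30 kb) splits
(promoters excluded).

## Synthetic data

The generator reproduces the study design: 6 RNA / 5 ATAC cell types,
2 hybrid lines × 2 replicates, feature totals negative binomial
(size 20) around depth × log-normal(0, 1) expression weights, allelic
split binomial, fold-change classes 70% null / 15% shared / 15%
specific-to-one-cell-type with N(0, 1) log2 effects, contamination
adding round(f·N/(1−f)) chimpanzee counts per feature, and mapping
bias as a ±2 log2 distortion of human counts for 5% of features under
exactly one reference. Default depth 10^6 read pairs per sample
(a scaled-down stand-in for ~10^8-read libraries over ~20k genes, at
the same ~500 reads-per-feature order of magnitude). Population ASE
draws individual ratios 0.5 + N(0, σ_g) (default σ = 0.05) sampled
binomially at depth 100 per gene, with optional directional gene-set
shifts and companion per-replicate interspecies fold-changes
(noise sd 0.1).

What it does **not** emulate — and hence what passing tests do not
show about real data: read-level artifacts (the dual-reference tables
are identical outside the designated mapping-bias subset, so the
concordance filter's false-removal rate on real remapping noise is not
measured here), fragment-level ATAC structure, correlated expression
across features, line-specific differentiation effects beyond what the
replicate filters absorb, and genome-scale feature counts.

## Problem sizes and numerical conventions

Simulation-based tests use 1,500–5,000 features at depth 10^6 and the
selection analyses 400 genes × 40 individuals × 100 seeded runs with
1,000 permutations per set — sizes chosen so the full suite and the
acceptance script each complete in minutes on one core while keeping
Monte-Carlo error well inside the asserted margins. All randomness
flows from a single integer seed via `numpy.random.SeedSequence`
spawning. Ties are always broken deterministically (feature id, rank
order, vocabulary order, first occurrence). Degenerate inputs resolve
to explicit conventions rather than NaN wherever a downstream
denominator needs them: zero-total binomial tests give p = 1 with a
warning, zero-variance Welch tests give p = 1, identical state medians
give z = 0, dEE of a zero target is 0. BH q-values are capped at 1;
NaN p-values propagate and are excluded from the BH denominator.

## Known limitations

- No overdispersion modeling in the allelic test (see above); the
  filters substitute for a line covariate.
- The global-ratio normalization couples features (see QC section);
  small-|L| calls at extreme depth inherit a systematic component.
- The contamination estimate f̂ is biased when many features carry real
  divergence; the correction itself (global balance) is exact
  regardless.
- The Mann–Whitney constraint comparison uses magnitude deviations
  |ratio − 0.5|; a signed-ratio variant is configurable but untested
  against data.
- Peak-calling itself is out of scope: narrow peak specificity takes a
  boolean call matrix as input.
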