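# Methods

## The scientific setting

In an F1 hybrid, both parental alleles of every gene are transcribed inside
one nucleus and therefore see exactly the same trans-acting environment
(transcription factors, signaling state, chromatin machinery).  The ratio of
allele-specific read counts consequently isolates *cis*-regulatory
divergence between the two parental strains: if a gene's expression differs
between the parents but the F1 alleles are balanced, the difference must be
*trans*; if the F1 allelic ratio reproduces the parental ratio, it is *cis*.
This package implements that comparative logic for a stress-response design:
a panel of inbred strains (the maternal reference strain, a B6 analog,
first) assayed under a control condition and under tunicamycin (TM)-induced
ER stress, plus a set of F1 crosses sharing the maternal strain.

## Statistical machinery

All count tests are exact.  Two-sided p-values for the binomial and Fisher
tests use the minimum-likelihood definition (sum of point probabilities no
larger than the observed outcome's, with a relative tie tolerance of 1e-7);
the hypergeometric and binomial point masses are evaluated in log space via
`gammaln`, and the test suite verifies agreement with exact-rational
enumeration to 1e-10 for all problem sizes up to n = 60.  Benjamini-Hochberg
q-values are the standard step-up construction (sorted p * m / rank, running
minimum from the tail, capped at 1).

### Induction calling (parental panel)

Counts are normalized between samples with trimmed-mean-of-M-values (TMM)
factors: reference sample = the one whose upper-quartile count fraction is
closest to the panel mean; M values doubly trimmed (30% per M tail, 5% per
A tail) and combined with delta-method precision weights; factors rescaled
to geometric mean 1.  Sample QC projects each strain's log-CPM profiles on
the first two principal components, partitions them by a deterministic
2-means, and removes samples whose cluster disagrees with their condition
label — but only when both clusters have a two-thirds condition majority,
the majorities differ, and the clusters are separated by at least twice the
within-cluster RMS spread.  Overlapping condition clouds therefore yield no
removal, and any removal that would leave fewer than two replicates in a
condition raises an error instead.

The TM-vs-control test per gene is an exact conditional negative-binomial
test on library-equalized pooled counts (counts scaled to one common
reference library, summed within condition and rounded): given a common
dispersion phi, the two group sums are NB with sizes n_group/phi and a
shared success probability, so the conditional law of one sum given the
total is parameter-free and can be enumerated exactly; phi = 0 degenerates
to a binomial split.  The common dispersion is a method-of-moments value:
per gene and replicate group, phi_g = (s² − m)/m², averaged over genes with
mean >= 20 (the per-gene estimates are scale-free, so highly expressed genes
do not dominate).  A gene is *ER-stress induced* in a strain when its point
estimate is at least 1.5-fold up and its within-strain BH q-value is <= 1%.
This is a deliberate methodological substitution for a generalized-linear
count-model fit: same intent (normalized count-based differential
expression), simpler and exactly reproducible machinery; it is validated by
simulation recovery, not by equality with any particular fitted model.

Strain effects on the TM response use the replicate-level log2 fold change
y_ij = log2(TM_ij / median control_i) (0.5-CPM offset on both terms;
zero-median genes dropped per strain) in a one-way ANOVA across strains, BH
at 1% FDR.  The co-response network connects genes whose fold-change
profiles correlate (Spearman, p < 0.05), with rho as edge weight.

### SNP filtering and informativeness (F1 data)

Per-record: allelic observations with maternal+paternal coverage below 4
are dropped.  Per-SNP: any SNP flagged third-allele, repeat-region,
near-indel, exon-intron-junction or non-monoallelic-in-parents is dropped in
all samples of its cross.  Coverage >= 4 is enforced per sample (the
stricter of the two possible readings).  Replicates are pooled, and a gene
is informative for a cross when it retains >= 2 discriminating SNPs and its
pooled maternal+paternal total exceeds 20 (cis/trans analysis) or 50 (ASE
analysis), within each condition analyzed.

### Cis/trans classification

Per cross and condition, three exact tests per informative gene:

1. **P** — parental differential expression: binomial test of the pooled
   maternal-strain count against the share of the maternal strain in the
   combined TMM-effective library sizes;
2. **F1** — allelic imbalance: binomial test of the pooled maternal allele
   count against 0.5;
3. **T** — ratio comparison (trans test): Fisher test of parental counts
   (standardized to the mean of the two effective library sizes and
   rounded; the rounding's effect is bounded in tests) against the F1
   allele counts, applied only to genes significant in step 1 (either P or
   F1), with BH within that subset.

BH is applied within each family; the significance pattern at FDR 0.1% maps
to: (P,F1,¬T) cis; (P,¬F1,T) trans; (P,F1,T, same sign) cis+trans;
(P,F1,T, opposite) cis×trans; (¬P,F1,T) compensatory; none conserved; all
other patterns ambiguous.  Signs are log2(maternal/paternal) ratios with
the maternal/reference strain in the numerator.  Magnitudes: cis = |log2 F1
allelic ratio|, trans = |log2 standardized parental ratio − log2 F1 allelic
ratio| (0.5 offsets for zero-count stability); %cis = cis/(cis+trans).
Conditions are always analyzed separately; a gene's condition pattern
(both / control-only / TM-only / neither) is derived per effect type.

### ASE change and the allelic fold decomposition

A TM-induced shift in allele-specific expression is a Fisher test on
[(maternal, paternal) control; (maternal, paternal) TM] pooled counts, BH
across genes within a cross at a default 5% FDR (the threshold is an
explicit package choice, configurable and recorded in output headers).  The
total linear fold change decomposes into allele-specific folds via
fold(allele) = total × prop_TM/prop_control, with the identity
Σ prop_control(allele)·fold(allele) = total; inverting it reconstructs the
post-stress allelic state from a control proportion and two allele folds.

### Shared regulatory differences

A gene informative in >= 2 crosses carries a *shared* difference when the
same category (cis with cis, trans with trans) appears in >= 2 crosses;
direction concordance is reported but not required, since opposite-direction
allelic imbalances still indicate paternal strains diverging from the
reference at the same locus.  The strain effect on a shared difference is a
Pearson chi-squared homogeneity test on the K×2 pooled allele-count table of
the sharing crosses (counts, not ratio estimates, to preserve exact
sampling), BH at 5% FDR.  The control-vs-TM sharing contrast is a 2×2
Pearson chi-squared on shared/unique counts, overall and stratified by the
number of informative crosses.

## The synthetic-data generator

The generator emulates a 13-genotype × 2-treatment × 3-replicate MEF
experiment.  Per gene it draws a relative abundance (log-normal, sd 1.5 on
the log2 scale), a per-strain induction effect (20% of genes induced; of
those 10% in all strains, 40% in one, the rest in an intermediate subset;
log2 effects uniform on [0.7, 3.5], with strain heterogeneity for 30% of
induced genes), and a regulatory architecture per cross: static cis (10%),
static trans (5%), combined cis+trans (2%), compensatory (2%), TM-only cis
(5%) and TM-only trans (2%), with |log2 effects| uniform on [0.5, 2] and
random sign.  Static cis/trans effects are shared across >= 2 crosses with
equal magnitude 40% of the time; TM-only effects are always private to one
cross, which is what makes stress dilute cross-sharing.  Parental counts
are negative binomial (default dispersion 0.05) around strain × condition
means in which the paternal strain's mean is scaled by 2^−(c+t); F1 allelic
counts are binomial around 2^c/(2^c+1), decomposed over a cross-specific
SNP set (1 + Poisson(3) SNPs per gene, Dirichlet-like weights) and three
replicates, with an optional beta-binomial switch to study allelic
overdispersion.  5% of SNPs carry injected quality flags (with distorted
allelic signal) and 3% of records are forced below the coverage-4 threshold,
to exercise the filters.  Library sizes default to 1e7 (parents) and 2e6
(allelically informative F1 reads) per sample; neither the real study's
depths nor its dispersion are published, so these are plausibility choices,
not fidelity claims.  The induction truth table records the *net* per-strain
TM log2 fold change — the drawn induction effect plus, for cross fathers,
the expression shift contributed by condition-specific regulatory effects —
because that is the quantity induction calling estimates.

What the generator does **not** model: read-level artifacts (mappability,
alignment bias), imprinting / parent-of-origin effects (single cross
direction), gene-wise dispersion variation, and correlated expression
between genes.  Passing recovery tests therefore demonstrates that the
inference machinery is correct under its own sampling assumptions, not that
those assumptions hold for any particular real dataset.

## Benchmark protocols and their problem sizes

The recovery benchmarks (in `cistrans.benchmarks`) fix the study
conditions:

* **Category recovery** — 2,000 genes, one cross, pooled allelic coverage
  500 per gene and condition, parental depth matched to ~500 pooled reads
  per strain and condition, |log2 effects| = 1, Poisson sampling
  (dispersion 0), FDR 0.1%.  Poisson sampling is used deliberately: the
  binomial and Fisher tests assume multinomial read sampling, and the
  benchmark measures the correctness of the hierarchical classification
  under its own model.  Overdispersed counts violate that assumption — the
  same caveat that applies to the real method — and the effect can be
  studied with the generator's dispersion and beta-binomial switches.
* **Condition-specific architecture** — the same sampling with five
  crosses, static cis effects shared half the time, TM-only cis effects
  cross-private.
* **Induction operating characteristics** — the full default configuration
  (8 strains, 5 crosses, 2,000 genes, NB dispersion 0.05), sensitivity
  measured at net true log2 fold change >= log2 3 and empirical FDR against
  generative nulls.
* **ASE null calibration** — a static architecture with no TM-only
  effects, 800 genes, coverage ~300.

## Numerical choices

* Tie tolerance 1e-7 (relative) in minimum-likelihood two-sided sums.
* p-values floored at the smallest positive double; ANOVA with zero
  within-group variance but non-zero between returns (inf, 0.0) rather
  than dividing by zero.
* Log-ratios use a 0.5-count offset; fold-change estimates use a 0.5-CPM
  offset.
* Pooled pseudo-counts are rounded to integers before exact testing.
* The 2-means used in QC is deterministic (centers initialized at the two
  most distant points), so the whole pipeline is a pure function of the
  seed.
* The ">20"/">50" coverage rules are strict inequalities on pooled totals;
  per-SNP coverage >= 4 is enforced per sample.

## Known limitations

* Exact binomial/Fisher machinery is anticonservative under count
  overdispersion; with the default NB dispersion of 0.05 the parental
  tests fire liberally and many truly-cis genes are labeled trans or
  ambiguous.  This mirrors the method's real-data caveat; the package
  surfaces it (dispersion diagnostics, beta-binomial switch) rather than
  replacing the tests.
* TMM can only partially correct an extreme one-sided composition shift
  (e.g. >20% of the library induced several-fold in one direction).
* The common-dispersion NB test ignores gene-wise dispersion variation.
* ANOVA on log fold changes assumes roughly equal within-strain variance.
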