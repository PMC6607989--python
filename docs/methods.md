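# Methods

`rarevar` implements a prioritization pipeline for low-frequency exonic
variants in candidate genes of a complex disease, built around a
family-plus-cohort design: variants are first filtered for segregation with
disease in sequenced families, then screened for frequency excess in an
unrelated patient cohort against public reference panels, and finally
assessed with two gene-level burden statistics.

## Family filtering cascade

Input is a multi-sample VCF of whole-exome calls for the family members, a
PED pedigree with affection status, and a candidate gene list.  The cascade
keeps a variant when:

1. its gene is in the candidate set and its consequence class is
   exonic/UTR (missense, synonymous, stop-gain, frameshift, start-loss,
   5′/3′ UTR);
2. its minor allele frequency (MAF) in a designated *primary* reference
   panel is ≤ `maf_max` (default 0.04), or the panel does not report it at
   all — novel variants pass.  The threshold is deliberately applied to a
   single panel rather than the maximum over panels: a max-rule would
   reject variants that the design intends to keep (a variant can sit just
   above 4% in one panel and well below in the primary one);
3. genotypes backed by read counts satisfy the read-fraction calling rule:
   with alternate-read fraction *f*, a call is heterozygous when
   0.40 ≤ *f* < 0.85 (the lower boundary is inclusive), homozygous-alternate
   when *f* ≥ 0.85, reference otherwise.  Only the heterozygous lower bound
   is externally specified; the 0.85 hom-alt boundary is this package's
   default and is configurable.  Zero-depth sites become missing calls with
   a warning, and missing calls are treated as non-carriers throughout.

Segregation labels per variant: *affected-only* (every sequenced carrier is
affected; false when there are no carriers, and a carrier with unknown
phenotype breaks the label), and *transmitted* (some carrier pair is an
affected parent and affected child).  Selection for cohort follow-up keeps
all transmitted variants plus — optionally — family-private novel variants
(no panel reports a positive frequency) carried by at least one affected
member and restricted to protein-altering classes (missense, stop-gain,
frameshift, start-loss).  The protein-altering restriction is a design
choice: a private variant with no frequency information is only worth
genotyping in a cohort when it can plausibly change the protein; without it
the rescue would also promote private UTR variants.

The MAF filter is applied before the carrier criteria; the final selected
set is invariant to that order.

## Cohort frequency comparison

For each selected variant the cohort MAF is `alt_alleles / (2 ×
non-missing patients)`.  The default test treats the reference panel MAF
p₀ as a known population proportion:

    z = (p̂ − p₀) / sqrt(p₀(1 − p₀)/n),   p = two-sided normal tail,

with n the cohort allele count.  This *fixed-reference* form is the package
default because panel sample sizes are orders of magnitude larger than the
cohort (and often unpublished at the variant level); the classical
pooled-variance two-proportion z-test is available when the panel allele
count is known, and the two converge as the panel grows.  The normal
approximation is anti-conservative for very small p₀ (the calibration test
documents this); at p₀ ≥ 0.05 and n = 240 the nominal 5% level is accurate
to within Monte-Carlo error.

A variant enters the multiple-testing family when at least one panel
reports it at a frequency in (0, 1) and it segregates locally — carried by
the cohort or present in the ancestry-matched panel (by default the first
panel supplied).  A variant absent from both the cohort and the matched
panel has nothing to test.  The Bonferroni threshold is α divided by the
size of this family (reports render it at 4 decimals).

Allelic odds ratios are computed from frequencies, OR = [p̂/(1−p̂)] /
[p₀/(1−p₀)]; a Woolf 95% CI, exp(ln OR ± 1.96·√Σ1/cell), is added only
when full 2×2 allele counts are available (zero cells get the
Haldane–Anscombe 0.5 correction and are flagged).  With frequency-only
panels the CI is omitted rather than fabricated from an assumed n.

Per-patient combinations: the carried-variant multiset of every patient
(het/hom flagged) and the histogram of patients by number of distinct
carried variants.  The histogram satisfies Σ k·count(k) = number of
(patient, variant) carrier pairs.

## Burden statistics

**Permutation enrichment.**  The statistic is the low-frequency variant
density of a gene set: Σ variant counts / Σ longest-isoform exonic lengths
(the longest isoform is the one maximizing total exon length; ties break
to the lexicographically lowest isoform id).  The null distribution comes
from `n_perm` uniform random gene sets of the same size drawn without
replacement from the annotated universe (independently across replicates;
the observed genes are included in the sampling pool by default, switchable).
Tie rules for the empirical p-value: `strictly_greater`
(#{null > observed}/n, the literal "proportion of replicates higher than
observed", which can return 0), `greater_or_equal`, and `plus_one`
((r+1)/(n+1) with r = #{null ≥ observed}), which never returns 0 and is
uniform under a null observed set.  The length-normalized density is the
primary statistic; the raw count is available because the two differ only
through the length normalization and some users may want the literal count.

**Null-variant proportion.**  A variant is *null* (loss-of-function) iff
its consequence is stop-gain or frameshift; start-loss is excluded — it
removes initiation of one transcript rather than truncating the product,
and is screened with the missense set.  Proportions of null variants
between two collections are compared with the maximum-likelihood (G)
chi-square on the 2×2 table, G = 2·ΣO·ln(O/E) with expectations from the
margins, p from χ²(1); zero cells contribute nothing, fully degenerate
margins raise.

## Synthetic data

The generator emulates the study conditions: three nuclear families (11
sequenced members), a 120-patient unrelated cohort (240 alleles) at ~15
independent low-frequency sites, reference panels sampled binomially at
their stated allele counts (e.g. 214 for the ancestry-matched panel), and
a gene universe with Poisson(5)+1 exons per gene and log-normal exon
lengths (log-mean 5.0, log-sd 0.6; median exon ≈ 148 bp).  Founder
genotypes are binomial in the population MAF; offspring inherit one allele
per parent; read depths are Poisson (mean 100) with alternate fractions
0/0.5/1 by genotype.  Cohort genotypes are Hardy–Weinberg draws, optionally
inflated by a planted allelic odds ratio; planted gene sets multiply the
per-base variant rate (default 5×10⁻⁴ per exonic base).

What the generator does **not** model: linkage disequilibrium between
sites (the screened combinations in the motivating design are on different
chromosomes), sequencing error and allelic bias, population structure, and
genotyping failure patterns.  Passing tests therefore demonstrate the
statistical behaviour of the methods under idealized sampling, not
robustness to artifacts of real sequencing data.

Machine-readable copies of the study's published tables ship as package
fixtures so the whole pipeline runs with no downloads.  The pedigree
affection labels are not printed as text in the source figure; the shipped
pedigree file carries the unique assignment consistent with all published
constraints and is explicitly flagged as back-derived.  One duplicated
carrier row at the ADAMTS3 4:73414590 site is stored with an `ambiguous`
flag and excluded from the 20-variant working set.

## Numerical and scale choices

* Frequencies are fractions internally and 2-decimal percents in reports;
  fixture values are used exactly as printed, never re-rounded.
* VCF positions are 1-based, annotation intervals 0-based half-open; the
  single conversion lives in `vcf_pos_in_interval`.
* Multi-allelic records split per alternate allele; the split call keeps
  its own allele depth, and all other reads count toward the calling
  total.
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator and the permutation test are bit-reproducible under a fixed
  seed.
* Test-suite problem sizes are reduced-scale by design (universes of
  200–300 genes, 99–2000 permutation replicates, 100–500 simulation
  replicates, cohorts of 120–240 alleles): large enough for the binomial /
  KS tolerances used, small enough to keep the suite fast on one CPU.
* The calibration tolerances are 3 Monte-Carlo standard deviations for
  frequency/permutation estimates and a 99% binomial band for rejection
  rates.

## Known limitations

* The fixed-reference z-test ignores sampling noise in the panel MAF;
  for the ancestry-matched panel (hundreds of alleles) the pooled mode is
  the statistically safer choice and is provided.
* The permutation statistic treats per-gene variant counts as given; it
  does not model discovery effort differences between genes.
* The G-test applies to counts of discovered variants, not carriers;
  discovery in a fixed sequenced window is assumed exchangeable between
  the compared collections.
* Consequence classes are taken from the input annotation; the package
  does not re-annotate from transcript sequence.
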