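# Methods

## The problem and the overall model

Purebred dog cohorts confound trait and ancestry: a breed-defining trait is
carried by every member of a handful of closely related breeds and by almost
nobody else, so the "case" group *is* a clade.  Two consequences shape the
design of this package.  First, association statistics are genomically
inflated (λ far above 1), and mixed-model corrections are unattractive
because the causal variant itself is identical by descent across the case
breeds — aggressive relatedness correction would absorb the signal.  The
screen therefore uses plain genomic control: the genome-wide distribution of
1-df statistics estimates λ, and every statistic is divided by it.  Second,
a breed-defining recessive variant is expected to be (nearly) fixed in case
breeds and (nearly) absent elsewhere, which motivates the complementary
fixation scan (> 90% case/control allele-frequency difference, chained into
physical regions and ranked by span).

## Synthetic cohort generator

The generator is the package's stand-in for a deep-sequenced multi-breed
cohort; it is first-class, tested code, not a fixture.

**Population structure.** Variant ancestral frequencies are uniform on
[0.05, 0.95].  Per-breed frequencies follow the Balding–Nichols model: for
ancestral frequency p and divergence F, each breed draws from
Beta(p(1−F)/F, (1−p)(1−F)/F), with mean p and variance F·p(1−p).  F = 0
short-circuits to p exactly.  Genotypes are Hardy–Weinberg within breed.

**Defaults (the study conditions).** 21 breeds; sizes (5, 3, 2) for the
three case breeds (10 cases) plus twelve breeds of 5 and six of 4 (84
controls); 6 trios whose offspring bring the cohort to 100 samples and are
excluded from association; F = 0.2, which yields λ ≈ 2.4–2.7 under the
mean-of-statistics estimator — the strong-inflation regime the method is
designed for; per-cell missingness 0.064 (a ~93.6% genotyping rate); 20,000
variants at fixed 3-kb spacing over 38 autosome-like chromosomes for the
scaled-down screen.  These values are fixed once here; tests and the
acceptance script use them unchanged.

**Linkage disequilibrium.** Variants are tiled into blocks of 5 sharing a
latent "core" genotype; each cell copies the core with probability 0.8 and
is otherwise redrawn under Hardy–Weinberg.  This produces the within-window
redundancy that VIF pruning exists to remove, without pretending to model
recombination.

**The implanted causal variant.** One mid-genome variant is rewritten as a
1-bp deletion, homozygous alternate in every case-breed sample and at
frequency 0 in controls; 20 variants on each side are fixed alternate in
case breeds and segregate at frequency 0.05 in controls, emulating the long
identical-by-descent haplotype that surrounds a breed-defining variant.
Two deliberate idealizations reflect the scenario being emulated — a causal
site that survived QC: the implanted region carries nominal passing
annotation values, and the focal site is exempt from the missingness mask
(with i.i.d. 6.4% missingness it would otherwise exceed the 10% missingness
cutoff in ~6% of cohorts).  Flank variants keep ordinary missingness.

**Trios and genotype error.** Offspring genotypes are formed by one
Bernoulli(g/2) allele from each parent; afterwards each offspring cell is
corrupted with probability `genotype_error_rate` (default 0.05) to a
uniformly chosen different dosage.  Only a subset of corruptions is
detectable as a Mendelian inconsistency, so the detected per-meiosis rate
(≈ 1.6% at the default) is an index of, not an estimate of, the underlying
error rate — exactly how such audits are used in practice.

**Site annotations.** Each of QD, FS, SOR, ReadPosRankSum, DP, MQ,
MQRankSum, InbreedingCoeff is drawn from a unit-scale distribution centred
well inside its pass region; a per-field fraction (default 0.02) is pushed
beyond the threshold, so ~15% of sites fail at least one criterion.  Float
annotations are materialized at single precision because VCF Float INFO
fields are float32 in htslib; the writer prints them with `%.9g`, making the
write→read round trip bit-exact.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: coalescent or recombination realism, allele-
frequency spectra from mutation/drift balance, sequencing-depth-correlated
missingness or genotype error, batch effects, and annotation values that
covary with genotype quality.  The generator is designed to make the
*statistical machinery* falsifiable, not to imitate a sequencer.

## Numerical and procedural choices

- **Hard filters** implement the quoted strict inequalities literally: a
  site exactly at a threshold passes.  MQ/MQRankSum apply to SNVs only,
  InbreedingCoeff to indels only, the DP cap to both.  A missing annotation
  skips its criterion with a logged warning rather than failing the site.
  The DP criterion is the cohort-level INFO depth (one constant for the
  whole cohort).
- **Indel recoding** maps any multi-character allele pair to REF=A/ALT=T —
  any fixed injective assignment preserves ref/alt contrast — and keeps the
  original alleles in sidecar columns.  The operation is idempotent.
- **Allelic test.** Zero-margin tables return χ² = 0, p = 1 (uninformative,
  keeps the table rectangular); no continuity correction.  A perfectly
  separated table attains χ² = N exactly, which the tests use as an
  analytic anchor.
- **Genomic control.** Default estimator is the mean of the statistics
  (E[χ²₁] = 1); the median/0.4549 estimator is available as `median` and is
  recorded in the output metadata.  λ is floored at 1 before correction
  (no deflation) unless flooring is disabled.  On discrete allelic tables
  at ~190 alleles the corrected test is mildly *conservative* (measured
  type-I ≈ 0.044 at nominal 0.05) because the attainable p-values form a
  staircase; calibration on continuous χ²₁ draws is exact to binomial
  noise.
- **Significance threshold.** The raw-p equivalent of a corrected alpha is
  t = SF(λ·Q(1−α/n)), with SF/Q the χ²₁ survival/quantile functions — the
  exact inverse of the correction chain, verified by round-trip in tests.
- **VIF pruning** removes, within each 50-variant window (step 5, never
  spanning chromosomes), the variant with the largest VIF until all VIFs
  are ≤ 2, recomputing after every removal; ties remove the larger index,
  exact collinearity counts as infinite VIF, monomorphic variants get
  VIF 1, and missing dosages are mean-imputed per variant.  VIFs are read
  off the diagonal of the inverse correlation matrix, with a per-variant
  least-squares fallback when the matrix is numerically singular; a
  brute-force least-squares oracle checks the kept sets exactly.  One
  caveat is documented deliberately: the *global* sliding-window procedure
  is not idempotent in general — removal is global while VIF acceptance is
  window-local, so re-running on the kept set regroups distant correlated
  variants into common windows and can remove more.  Within a single
  window idempotence holds (dropping regressors can only lower R²), and
  that is the property the tests assert.  The pruning subset uses its own
  thresholds (genotyped > 95%, MAF > 5%), separate from the association
  filters (10% / 1%).
- **Mendelian audit.** A trio-site errs when the offspring dosage cannot be
  built from one allele per parent; sites with any missing member are
  skipped.  The per-meiosis denominator is 2 × evaluated trio-sites (two
  meioses per offspring genotype).
- **Fisher's exact test** is enumerated in exact integer arithmetic
  (binomial coefficients; one rational division at the end), so the
  two-sided rule — include every table whose point probability is ≤ the
  observed one — needs no floating-point tie tolerance.  The r×2 genotypic
  test enumerates all tables with the observed margins the same way.
- **Penetrance display** rounds half-up to one decimal; the raw fraction is
  always retained because published tables are inconsistent (some cells
  truncate, e.g. 92.16% shown as 92.1).
- **Consequence caller.** Frameshifted translation continues through the
  provided 3'UTR; a transcript without a downstream stop returns a flagged,
  non-failing call with undefined lengths.  When the first novel codon is
  itself a stop, the call is a clean truncation (new residue `Ter`,
  0 novel residues).  Two notations are rendered because the legacy fsX
  convention counts novel residues while HGVS fsTer counts the stop
  (k = novel + 1); the structured fields, which satisfy
  `mutant_length = fs_position − 1 + n_altered`, are the source of truth.
  Only single-transcript, CDS-internal variants are in scope.
- **Dendrogram.** Agglomerative clustering (UPGMA by default) of the 1−IBS
  matrix; Newick branch lengths are merge-height differences, so two
  samples form a cherry with branches of half their distance.

## Problem sizes used by the tests and acceptance script

The shipped checks run the full screen at 20,000 variants × 100 samples
across 20 seeds (the scaled-down analogue of a multi-million-variant
cohort), genomic-control calibration on 100,000 χ²₁ draws, the Fisher
enumeration grid over all 2×2 tables with total ≤ 40, 50 random 8-variant
pruning windows against the least-squares oracle, and 1,000 random
transcript/deletion pairs against a residue-comparison oracle.  These sizes
are the package's own choices: large enough that every pass/fail criterion
is far from its Monte-Carlo noise floor, small enough to run routinely.

## Known limitations

Single bi-allelic causal variant, autosomal, fully penetrant at the
breed-definition level; no covariates, no mixed models, no phasing or
formal runs-of-homozygosity, no genome-wide consequence annotation.  The
generator's simplifications are listed above; in particular λ values from
the generator depend on its FST and breed-size settings and are not
comparable across configurations.
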