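# wgva — whole-genome variant association for breed-structured cohorts

`wgva` is a compact, tested pipeline for mapping a **breed-defining recessive
trait** (for example the screw-tail phenotype of bulldog-related breeds)
directly from whole-genome sequencing genotypes, without a SNP array step.
Purebred cohorts are extremely stratified — cases and controls are different
breeds — so a naive case/control test is massively inflated.  The pipeline
implements the pragmatic screen used in this setting:

1. **Site filtering** — GATK-style hard filters on the joint call set
   (QD < 2, FS > 60, SOR > 4, ReadPosRankSum < −8, DP > 3105 for all sites;
   MQ < 40 and MQRankSum < −12.5 for SNVs; InbreedingCoeff < −0.8 for
   indels), restriction to bi-allelic variants on characterized chromosomes,
   and recoding of indel alleles to single characters (REF→A, ALT→T) so SNVs
   and indels are tested uniformly.
2. **Cohort QC and structure** — per-variant missingness (≤ 10%) and MAF
   (≥ 1%) filters; identity-by-state distances
   `d(i,j) = Σ|gᵢ−gⱼ| / (2·n_shared)` with a UPGMA dendrogram (Newick); LD
   pruning by **variance inflation factor** (VIF = 1/(1−R²) of each variant
   regressed on the others in a 50-variant window, step 5, threshold 2);
   and a trio Mendelian-error audit (errors per meiosis) as a genotyping
   accuracy index.
3. **Allelic association with genomic control** — per variant the 2×2 allele
   table (a, b; c, d) is tested with the 1-df Pearson statistic
   `χ² = N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`; the genomic inflation factor λ
   (mean of the statistics, or median/0.4549) rescales every statistic
   (`χ²_GC = χ²/λ`), and Bonferroni correction uses the VIF-pruned variant
   count as the number of independent haplotypes.
4. **Fixation scan** — variants with > 90% case/control allele-frequency
   difference are chained into candidate regions (gap ≤ 1 Mb, ≥ 10
   variants), ranked by physical span to prioritize long fixed haplotypes
   consistent with identity-by-descent.
5. **Segregation and penetrance** — per-breed genotype counts, allele
   frequencies, penetrance among homozygotes, and Fisher's exact test
   (integer-exact enumeration; 2×2 recessive pooling or an r×2 genotypic
   test).
6. **Consequence calling** — protein-level calls for coding indels on a
   transcript model: frameshift detection, first divergent residue, novel
   residue count to the new stop (which may lie in the 3'UTR), truncation or
   extension, rendered as `p.Pro684LeufsTer27` (HGVS) or `p.Pro684LeufsX26`
   (legacy).

Because deep-sequenced dog cohorts are rarely redistributable, the package
ships a first-class **synthetic cohort generator**: ~100 samples from 21
breeds with Balding–Nichols divergence (FST ≈ 0.2, which reproduces the
λ ≈ 2.5–3 inflation regime), block-structured LD, parent-parent-offspring
trios, per-cell missingness, GATK-style site annotations, and an implanted
case-breed-fixed recessive deletion riding on a long fixed flanking
haplotype.  Every stage of the pipeline is exercised end to end against it.

## Worked example

Run the whole screen on a simulated 8,000-variant cohort:

```bash
cat > run.yaml <<EOF
seed: 1
out_prefix: demo/screen
simulation:
  n_variants: 8000
  seed: 1
EOF
wgva run --config run.yaml
```

which prints the run accounting:

```json
{
  "simulated_variants": 8000,
  "samples": 100,
  "input_variants": 8000,
  "failed_hard_filters": 1040,
  "multiallelic_removed": 0,
  "after_site_filters": 6960,
  "qc_input": 6960,
  "removed_missingness": 350,
  "removed_maf": 1,
  "tested": 6609,
  "pruned_set": 1384,
  "mendel_mean_rate": 0.01780444325230607,
  "lambda": 2.7283974736438554,
  "n_tests_bonferroni": 1384,
  "fixation_passing": 25,
  "candidate_regions": 1,
  "top_variant": {
    "CHR": "chr19",
    "POS": 609000,
    "P": 8.687597730247793e-43,
    "P_GC": 1.0332691394868085e-16,
    "P_BONF": 1.430044489049743e-13
  },
  "segregation_p": 7.060660731096957e-15
}
```

Reading the numbers: 13% of sites fail the hard filters, ~5% more fall to
missingness/MAF, and 6,609 variants are tested.  Breed stratification
inflates the statistics (λ = 2.73); after genomic control the implanted
deletion is still the top hit genome-wide (raw p ≈ 8.7×10⁻⁴³, Bonferroni
p ≈ 1.4×10⁻¹³ over the 1,384 pruned haplotypes), it is the only variant
cluster passing the 90% allelic-difference scan (one candidate region, fully
case-fixed), and the recessive segregation test of its genotype table is
p ≈ 7×10⁻¹⁵.  Stage outputs (`.assoc.tsv`, `.regions.tsv`/`.bed`,
`.ibs.tsv`, `.tree.nwk`, `.prune.in`, `.mendel.tsv`, `.genotypes.tsv`,
`.manifest.json`) land next to the configured prefix, and
`demo/screen.manifest.json` records every parameter and output hash needed
to reproduce the run bit for bit.

Each stage is also a standalone subcommand on ordinary files:
`wgva simulate | filter | qc | assoc | scan | segregate | csq` — for example

```bash
wgva csq --fasta tx.fa --variants vars.tsv --cds-start 1 --cds-end 18 --out csq.tsv
```

annotates a 1-bp deletion at c.7 of an 18-nt toy CDS as `p.Pro3GlnfsX4`
(four novel residues, one-residue extension into the UTR).

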