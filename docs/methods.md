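# Methods

## Model and assumptions

The method treats every inbred strain as a single homozygous genome. A
variant site is a strain distribution pattern: each strain carries either
the reference allele, one alternative allele, or provides no usable
evidence. Fine-mapping a binary phenotype then reduces to set logic — report
every site at which one allele can be assigned to each phenotype group so
that at most thr1 strains of group 1 and thr2 strains of group 2 carry the
wrong allele. Both assignments (alternative allele in group 1 or in
group 2) are always tested; when both pass, the one with fewer total
discordances is reported, with ties resolved to the alternative allele in
group 1 so output is deterministic.

The approach assumes (i) genotypes are correct or flagged, (ii) the causal
variant is a SNV present in the genotype resource, and (iii) the phenotype
split is correct up to the allowed discordances. It makes no statistical
adjustment for strain kinship: closely related strains share long
haplotypes, so compatible variants come in blocks, which is why the locus
merge step exists.

## Genotype encoding

Each call is assigned to exactly one class by fixed precedence: low
confidence → missing → multiallelic → homozygous → heterozygous (first
match wins). The per-genotype confidence flag defaults to the `FI` FORMAT
key with value 0 meaning low confidence; files without the key are treated
as fully confident. At multi-allelic sites the retained alternative is the
ALT carried homozygously by the most strains (GT only — a low-confidence
homozygous call still counts toward choosing the retained ALT, since the
allele frequency is a property of the site; the call itself still encodes
NULL). Ties go to the first-listed ALT. Homozygous reference encodes 0,
homozygous retained-alternative 1, every other class NULL. Sites NULL in
every strain are dropped at load; indels and other non-SNVs are skipped and
counted. A configured reference strain absent from the sample columns (the
assembly strain, C57BL/6J for GRCm38) encodes 0 everywhere by definition.

NULL handling inside the compatibility test is a genuine policy choice the
encoding semantics do not determine. The default (`DISCORDANT`) counts a
NULL as a mismatch, so it consumes threshold budget and compatibility is
never declared on absent evidence; `IGNORE` drops the strain from the count
for that variant. The two differ only for variants with NULLs inside the
query groups.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| thr1, thr2 | 0 | discordant strains tolerated per group |
| null_policy | DISCORDANT | NULL counts as mismatch vs excluded per variant |
| max_gap | 1,000,000 bp | locus merge distance; matches the cis-window scale |
| flank | 0 bp | gene-span extension for overlap annotation |
| window | 1,000,000 bp | cis window half-width around the TSS |
| expression cutoff | 120 (intensity) | transcript kept if any mouse reaches it |
| min_group_size | 1 | smaller binarized group must reach this size |
| autosomes | 1–19 | chromosome filter when enabled |

Coordinates are 1-based closed intervals throughout (VCF/GFF convention);
BED export converts to 0-based half-open. Gene overlap is strand-agnostic;
strand only determines the transcription start site (start on +, end on −).

## Trait binarization

Quantitative traits are split into two strain groups by ordering strains
ascending on the minimum value over their mice (ties broken by strain
name), then choosing the rank r that maximizes the absolute gap between a
location statistic of all mice of strains ranked ≤ r and of those ranked
> r (ties to the smallest rank).

The statistic is the **mean** by default, and this choice is deliberate.
For bimodal data the mean gap is maximized exactly at the mode boundary:
moving the split point by one strain shifts the contaminated side's mean in
proportion to the effect size, so the objective profile is sharply peaked.
The median gap — the obvious robust alternative, offered as
`statistic="median"` — is nearly useless here: as long as each side's
median sits inside its majority mode, |median(high) − median(low)| equals
the mode separation at *every* crossing rank, the profile is flat up to
order-statistic effects of order σ that do not grow with effect size, and
the chosen rank degenerates to noise. Measured on synthetic bimodal traits
(20 strains, 2 mice each, 10σ separation), the mean rule recovers the
planted split for 99–100% of transcripts at group sizes 5–15, the median
rule for ~5–35% at any separation. Users wanting a robust objective should
increase mice per strain rather than switch to the median.

The cis scan applies this per transcript, skips transcripts whose smaller
group is below `min_group_size` (interpreted as the size of the smaller of
the two groups) or that lack a TSS, and fine-maps [tss − window,
tss + window] with group_low as group 1. Thresholds are clamped to
group size − 1 so one-strain groups remain queryable.

## Consequence and impact filtering

VEP-style `CSQ` INFO strings are parsed using the field layout declared in
the VCF header; `&`-joined terms are split and each mapped separately. When
no IMPACT field is present, impact is derived from the bundled
sequence-ontology term → severity table (the Ensembl Variation
categorization: HIGH, MODERATE, LOW, MODIFIER); unknown terms fall back to
MODIFIER with a warning, never an error. A variant passes an impact or
consequence filter if **any** of its annotations passes, matching how
variants (not annotations) are counted in practice.

## Combinatorics

The maximum number of genotype combinations for n strains is
Σ_{k=1..n} Σ_{j=1..k} C(k, j) = 2^(n+1) − n − 2, computed with exact
integer arithmetic (the closed form overflows 64-bit floats/ints around
n = 63; Python integers are exact at any n). The double summation is kept
as an independent cross-check. The count first exceeds 1,000 at n = 9 and
first exceeds 74,480,058 at n = 26; the count for n = 10 is 2,036. The
realizable number for a concrete panel is smaller because of kinship; no
kinship-adjusted count is attempted.

## Synthetic data

The generator emulates the structure of a strain-panel SNP resource at desk
scale: two 10 Mb chromosomes by default, GT and FI per genotype, optional
CSQ annotations, planted variants that realize an exact group-discordance
structure (exempt from noise), and background sites with fair-coin
genotypes plus per-call noise classes (low-confidence, missing,
multiallelic as a homozygous third allele, heterozygous) at configurable
rates. Truth tables store the encoded genotype vector, per-strain class
counts, and compatibility verdicts over a small threshold grid, evaluated
on the generated calls with the same classification rules the loader
applies — so end-to-end identity (generate → write → load → scan) is exact,
and noise rates are checked statistically (4σ binomial bounds), not
assumed. Identical specs (including seed) produce byte-identical files.

Expression fixtures draw each mouse from N(base + separation, σ) or
N(base, σ) depending on its strain's allele at the planted causal variant,
two mice per strain by default, base 200 on the intensity scale so the
expressed-transcript cutoff (120) keeps all rows unless set higher. The
eQTL cohort plants one causal variant per transcript within the cis window
of its TSS, with alternative-allele group sizes drawn uniformly from
5..n−5 — balanced-ish splits typical of a common cis haplotype — plus 2,000
unlinked background variants.

What the simulations do **not** model: linkage disequilibrium and kinship
(background genotypes are independent across sites and strains, so
compatible blocks and the block-like locus structure of real panels are
absent), allele-frequency spectra, shared noise between strains, and
expression normalization artifacts. Passing tests therefore demonstrate the
correctness of the encoding, predicate, merging and scanning logic and the
behavior of the binarization heuristic — not calibrated false-positive
rates on real panels, which are dominated by kinship.

## Numerical and degenerate-input choices

PCA uses only sites with no NULL in any panel strain (no imputation),
mean-centered 0/1 genotypes, full SVD; coordinates are reproducible up to a
sign per component. Fewer complete sites than components is an error.
Unsorted VCFs and panel strains missing from the header are fatal;
malformed genotype strings raise an error naming the variant and strain.
Empty variant lists merge to an empty locus list. Region strings accept
commas in numbers. Problem sizes in the test suite (random matrices up to
5,000 × 20, cohorts of 200 transcripts over ~2,200 variants) keep every
check exhaustive against brute-force oracles while running in seconds.

## Replicating published panel analyses

The pipeline applies unchanged to the public resources it is designed
around: the Sanger Mouse Genomes Project SNP VCF
(`mgp.v5.merged.snps_all.dbSNP142.vcf.gz`, GRCm38, 36 strains, `FI` flags)
for `finemap`/`qc`/`pca`, Ensembl GRCm38 GFF3 for gene annotation, and
ImmGen strain expression (GEO GSE60336 neutrophils, GSE60337 CD4⁺ T cells)
for `eqtl-scan`. These downloads are tens of GB and are deliberately not
part of the test suite; published per-phenotype variant counts additionally
depend on the exact VEP version and locus-grouping distance used, so exact
reproduction of printed counts is not claimed.

## Known limitations

SNVs only (no indels or structural variants); no phased or polyploid
genotypes; no X/Y/MT-specific logic; no statistical association testing or
kinship correction; locus counts depend on the configurable merge gap, for
which no canonical value exists; the binarization heuristic assumes an
approximately bimodal trait and degrades gracefully but silently when the
trait is not.
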