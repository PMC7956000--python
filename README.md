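# inbredfm

In silico fine-mapping of phenotypes using genome-wide genotypes of inbred
mouse strains.

## The problem and the approach

Inbred mouse strains are effectively clones: every animal of a strain is
homozygous at every variant site. When two groups of strains differ in a
phenotype — albino vs pigmented, calcifying vs resistant myocardium, high vs
low expression of a transcript — any causal single-nucleotide variant must
show a strain distribution pattern that segregates with those groups. With
whole-genome genotypes available for the common laboratory panels, the
candidate variants for a phenotype split can therefore be enumerated
directly, without breeding a single mouse.

Formally, genotypes are encoded per strain as 0 (homozygous reference),
1 (homozygous for the retained alternative allele) or NULL (missing,
low-confidence, heterozygous, or involving another allele — no usable
evidence for a homozygous panel). For a variant with genotype vector *g* and
strain groups *G₁*, *G₂* with discordance budgets *t₁*, *t₂*, the variant is
**compatible** iff there is an allele assignment (a₁, a₂) ∈ {(0,1), (1,0)}
with

&nbsp;&nbsp;&nbsp;&nbsp;|{s ∈ G₁ : g(s) ≠ a₁}| ≤ t₁ and |{s ∈ G₂ : g(s) ≠ a₂}| ≤ t₂.

Setting t₁ = t₂ = 0 demands perfect segregation; small budgets tolerate
phenotyping errors and imperfect binarization of quantitative traits. The
power of the approach comes from combinatorics: for *n* strains there are
2^(n+1) − n − 2 possible genotype combinations, so beyond ~10 strains a
compatible pattern is unlikely to arise by chance.

The package covers the full workflow:

- **`genotype_store`** — read multi-sample VCFs (pysam), classify each call
  (low confidence → missing → multiallelic → homozygous → heterozygous,
  first match wins), encode to {0, 1, NULL}, drop all-NULL sites, parse
  VEP-style `CSQ` consequence annotations, per-strain QC counts, strain PCA.
- **`finemap_core`** — the compatibility predicate and the genome-wide /
  region-restricted scan with impact and consequence filters.
- **`locus_gene`** — merge compatible variants into maximum-gap loci;
  annotate variants/loci with overlapping genes from GFF3/GTF, with
  optional flanking.
- **`combinatorics`** — exact genotype-combination counts.
- **`trait_tools`** — binarize quantitative per-mouse traits into two strain
  groups and drive cis-window (±1 Mb) scans across many transcripts.
- **`simulate`** — synthetic VCF / gene-model / expression fixtures with
  exact truth tables, so the whole pipeline runs at desk scale.

A thin CLI (`inbredfm finemap|annotate|loci|qc|pca|combinations|eqtl-scan|simulate`)
wraps the library; the `examples/` directory shows each capability as a
short script.

## Worked example

Nine strains, four albino; six candidate SNVs near the *Tyr* locus
(`examples/01_albinism_finemap.py`):

```text
panel: 4 albino vs 5 non-albino strains, 6 variants

thr1=0, thr2=0: 1 compatible variant(s)
  7:87493043 rs31191169 C>G impact=MODERATE discordant2=-

thr1=0, thr2=1: 2 compatible variant(s)
  7:87400000 sim_c A>G impact=MODIFIER discordant2=NZB/B1NJ
  7:87493043 rs31191169 C>G impact=MODERATE discordant2=-
```

With no discordance allowed, only rs31191169 — the known causal *Tyr*
missense SNP — segregates perfectly with albinism. Allowing one discordant
strain in the non-albino group admits one additional intronic variant.

The combination counts behind the power argument
(`examples/02_combination_growth.py`):

```text
n=10 strains:           2,036 combinations
n=27 strains:     268,435,427 combinations
panel size where combinations first exceed 1,000: 9
```

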