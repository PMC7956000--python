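"""Fine-map albinism across nine inbred strains.

Four albino and five non-albino strains, six candidate SNVs near the Tyr
locus on chromosome 7. A variant is reported when one homozygous allele can
be assigned to each phenotype group with at most thr1/thr2 strains carrying
the wrong allele.
"""

from inbredfm import FinemapQuery, finemap
from inbredfm.finemap_core import result_rows
from inbredfm.simulate import albinism_example

matrix, albino, others = albinism_example()
print(f"panel: {len(albino)} albino vs {len(others)} non-albino strains, "
      f"{len(matrix)} variants\n")

for thr2 in (0, 1):
    res = finemap(matrix, FinemapQuery(albino, others, thr1=0, thr2=thr2))
    print(f"thr1=0, thr2={thr2}: {len(res)} compatible variant(s)")
    for row in result_rows(res):
        print(f"  {row['chrom']}:{row['pos']} {row['rsid']} "
              f"{row['ref']}>{row['alt']} impact={row['max_impact']} "
              f"discordant2={row['discordant_strains_group2'] or '-'}")
    print()

# With no discordance allowed, only the causal Tyr missense SNP rs31191169
# segregates perfectly; allowing one discordant non-albino strain admits one
# additional intronic variant immediately upstream.
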