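"""How the number of genotype combinations grows with panel size.

Each variant shows one strain distribution pattern; the more patterns are
possible, the less likely any given phenotype split is matched by chance.
"""

from inbredfm import max_genotype_combinations, min_strains_exceeding

for n in (2, 5, 8, 10, 20, 27, 37):
    print(f"n={n:2d} strains: {max_genotype_combinations(n):>15,} combinations")

print()
print("panel size where combinations first exceed 1,000:",
      min_strains_exceeding(1_000))
print("panel size where combinations first exceed the ~74.5M SNV sites "
      "segregating in common panels:", min_strains_exceeding(74_480_058))

# Past ~10 strains a compatible pattern is already unlikely by chance; past
# the point where combinations outnumber variant sites, chance matches are
# essentially ruled out for fully segregating patterns.
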