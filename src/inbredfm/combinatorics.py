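"""Counting genotype combinations across inbred strain panels.

For n inbred strains each variant site shows a strain distribution pattern:
a subset of strains carries the alternative allele, the rest the reference.
With up to k of the n strains carrying alternative alleles, the maximum
number of distinct genotype combinations is

    sum_{k=1..n} sum_{j=1..k} C(k, j)  =  2^(n+1) - n - 2,

which grows exponentially in n. The more combinations exist, the less likely
a phenotype-compatible pattern arises by chance, which is what gives the
fine-mapping approach its power as panels grow. All arithmetic is exact
(Python integers), since 2^(n+1) overflows 64-bit at n >= 63.
"""

from __future__ import annotations

from math import comb


def max_genotype_combinations(n: int) -> int:
    """Maximum number of genotype combinations for ``n`` inbred strains.

    Closed form of the double summation over subset choices; exact integer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2 ** (n + 1) - n - 2


def max_genotype_combinations_bruteforce(n: int) -> int:
    """Literal double summation sum_{k=1..n} sum_{j=1..k} C(k, j).

    Independent of the closed form; used to cross-check it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(comb(k, j) for k in range(1, n + 1) for j in range(1, k + 1))


def min_strains_exceeding(threshold: int) -> int:
    """Smallest panel size n with max_genotype_combinations(n) > threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    n = 1
    while max_genotype_combinations(n) <= threshold:
        n += 1
    return n
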