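"""Two-group compatibility scan over a genotype matrix.

A variant is compatible with a two-group phenotype split when one homozygous
allele can be assigned to each group such that at most ``thr1`` strains in
group 1 and at most ``thr2`` strains in group 2 carry the wrong allele. Both
assignments — group 1 carries the alternative, or group 1 carries the
reference — are always tested; the method never fixes which group carries
which allele.

NULL genotypes carry no evidence. Under the default DISCORDANT policy a NULL
counts as a mismatch (it consumes threshold budget, so compatibility is never
declared on absent evidence); under IGNORE the strain is dropped from the
count for that variant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .genotype_store import NULL, GenotypeMatrix, Region, VariantRecord, parse_region
from .impacts import max_impact


class NullPolicy(enum.Enum):
    DISCORDANT = "discordant"
    IGNORE = "ignore"


@dataclass(frozen=True)
class FinemapQuery:
    """Two strain groups with per-group discordance budgets and filters.

    thr1/thr2 are the numbers of strains in group 1/group 2 allowed to carry
    an allele discordant with the phenotype while the variant is still
    reported. Impact and consequence filters pass a variant when ANY of its
    annotations passes.
    """

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    regions: tuple[Region, ...] | None = None
    thr1: int = 0
    thr2: int = 0
    impact_filter: frozenset[str] | None = None
    consequence_filter: frozenset[str] | None = None
    null_policy: NullPolicy = NullPolicy.DISCORDANT

    def __post_init__(self):
        object.__setattr__(self, "group1", tuple(self.group1))
        object.__setattr__(self, "group2", tuple(self.group2))
        if self.regions is not None:
            regs = tuple(r if isinstance(r, Region) else parse_region(r)
                         for r in self.regions)
            object.__setattr__(self, "regions", regs)
        if self.impact_filter is not None:
            object.__setattr__(self, "impact_filter", frozenset(self.impact_filter))
        if self.consequence_filter is not None:
            object.__setattr__(self, "consequence_filter",
                               frozenset(self.consequence_filter))
        if not self.group1 or not self.group2:
            raise ValueError("both strain groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError("strain groups must be disjoint")
        if not 0 <= self.thr1 < len(self.group1):
            raise ValueError("thr1 must satisfy 0 <= thr1 < |group1|")
        if not 0 <= self.thr2 < len(self.group2):
            raise ValueError("thr2 must satisfy 0 <= thr2 < |group2|")


@dataclass(frozen=True)
class CompatibilityResult:
    """Per-variant verdict: the allele assignment and the discordant strains."""

    compatible: bool
    allele1: int | None = None
    allele2: int | None = None
    discordant1: tuple[str, ...] = ()
    discordant2: tuple[str, ...] = ()


@dataclass
class FinemapResult:
    query: FinemapQuery
    variants: list[tuple[VariantRecord, CompatibilityResult]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def positions(self) -> list[tuple[str, int]]:
        return [(r.chrom, r.pos) for r, _ in self.variants]


def _mismatches(genotypes, strains, allele: int, null_policy: NullPolicy) -> list[str]:
    out = []
    for g, s in zip(genotypes, strains):
        if g == NULL:
            if null_policy is NullPolicy.DISCORDANT:
                out.append(s)
        elif g != allele:
            out.append(s)
    return out


def is_compatible(
    g1,
    g2,
    thr1: int = 0,
    thr2: int = 0,
    null_policy: NullPolicy = NullPolicy.DISCORDANT,
    strains1=None,
    strains2=None,
) -> CompatibilityResult:
    """Test both homozygous allele assignments against the discordance budgets.

    ``g1``/``g2`` are genotype values in {0, 1, NULL} for the two groups.
    When both assignments qualify the one with fewer total discordances is
    reported; on a tie group 1 is assigned the alternative allele.
    """
    g1 = list(g1)
    g2 = list(g2)
    strains1 = list(strains1) if strains1 is not None else [str(i) for i in range(len(g1))]
    strains2 = list(strains2) if strains2 is not None else [str(i) for i in range(len(g2))]
    best = None
    # assignment order puts (a1=1) first so that ties prefer it
    for a1, a2 in ((1, 0), (0, 1)):
        d1 = _mismatches(g1, strains1, a1, null_policy)
        d2 = _mismatches(g2, strains2, a2, null_policy)
        if len(d1) <= thr1 and len(d2) <= thr2:
            cand = CompatibilityResult(True, a1, a2, tuple(d1), tuple(d2))
            if best is None or len(d1) + len(d2) < len(best.discordant1) + len(best.discordant2):
                best = cand
    return best if best is not None else CompatibilityResult(False)


def _passes_filters(record: VariantRecord, query: FinemapQuery) -> bool:
    if query.impact_filter is not None:
        if not any(c.impact in query.impact_filter for c in record.consequences):
            return False
    if query.consequence_filter is not None:
        if not any(c.consequence_term in query.consequence_filter
                   for c in record.consequences):
            return False
    return True


def finemap(matrix: GenotypeMatrix, query: FinemapQuery) -> FinemapResult:
    """Return all variants compatible with the query's two-group split.

    Scans the region-restricted records (all records when no regions are
    given), applies the compatibility predicate at the query's thresholds and
    the annotation filters, and returns matches sorted by (chrom, pos).
    """
    panel = set(matrix.panel.strains)
    unknown = [s for s in (*query.group1, *query.group2) if s not in panel]
    if unknown:
        raise ValueError(
            f"unknown strains {', '.join(unknown)}; valid: {', '.join(matrix.panel.strains)}"
        )
    idx1 = [matrix.panel.index(s) for s in query.group1]
    idx2 = [matrix.panel.index(s) for s in query.group2]
    result = FinemapResult(query)
    for record in matrix.records:
        if query.regions is not None and not any(
            r.contains(record.chrom, record.pos) for r in query.regions
        ):
            continue
        if not _passes_filters(record, query):
            continue
        verdict = is_compatible(
            record.genotypes[idx1],
            record.genotypes[idx2],
            query.thr1,
            query.thr2,
            query.null_policy,
            strains1=query.group1,
            strains2=query.group2,
        )
        if verdict.compatible:
            result.variants.append((record, verdict))
    return result


def result_rows(result: FinemapResult) -> list[dict]:
    """Flatten a FinemapResult into TSV-ready row dicts."""
    rows = []
    for record, verdict in result.variants:
        rows.append({
            "chrom": record.chrom,
            "pos": record.pos,
            "rsid": record.rsid,
            "ref": record.ref_allele,
            "alt": record.alt_allele,
            "allele_group1": verdict.allele1,
            "allele_group2": verdict.allele2,
            "discordant_strains_group1": ",".join(verdict.discordant1),
            "discordant_strains_group2": ",".join(verdict.discordant2),
            "consequences": ";".join(sorted({c.consequence_term for c in record.consequences})),
            "max_impact": max_impact(c.impact for c in record.consequences) or "",
        })
    return rows
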