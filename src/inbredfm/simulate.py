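"""Synthetic genotype, gene-model and expression fixtures with known truth.

Everything downstream of this module can be exercised without the multi-GB
public resources it is designed for: the generator writes small multi-sample
VCFs with GT and FI per genotype (optionally VEP-style CSQ annotations),
plants variants whose alleles segregate with a chosen strain split (with a
controlled number of discordant strains per group), sprinkles NULL-class
noise (low-confidence, missing, multiallelic, heterozygous calls) at given
rates, and emits matching truth tables. Expression fixtures draw per-mouse
intensities from two normal components separated by a planted cis variant's
alleles, emulating bimodal gene expression across an inbred panel.

Identical specs (including the seed) produce byte-identical files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .finemap_core import is_compatible
from .genotype_store import (
    NULL,
    GenotypeMatrix,
    StrainPanel,
    VariantRecord,
    _chrom_key,
    classify_genotype,
)
from .impacts import impact_of
from .locus_gene import GeneModel

_NUCS = ("A", "C", "G", "T")

#: (thr1, thr2) grid for which truth tables record compatibility verdicts
THR_GRID = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class PlantedVariant:
    """A variant whose alleles segregate with a strain split, up to planted noise.

    ``alt_strains`` carry the alternative allele; ``discord1``/``discord2``
    strains of the alt/ref side are flipped to the opposite allele so the
    variant is compatible exactly from thresholds (discord1, discord2) on.
    """

    alt_strains: tuple[str, ...]
    discord1: int = 0
    discord2: int = 0
    consequence: str | None = None
    gene_id: str | None = None
    chrom: str | None = None
    pos: int | None = None
    rsid: str | None = None


@dataclass(frozen=True)
class FixtureSpec:
    strains: tuple[str, ...]
    n_variants: int = 100
    planted: tuple[PlantedVariant, ...] = ()
    null_rate: float = 0.0  # missing calls (./.)
    multiallelic_rate: float = 0.0
    het_rate: float = 0.0
    low_conf_rate: float = 0.0
    chrom_layout: tuple[tuple[str, int], ...] = (("1", 10_000_000), ("2", 10_000_000))
    #: strain split truth verdicts refer to; defaults to the first planted split
    truth_groups: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    seed: int = 0

    def __post_init__(self):
        for name, rate in (("null_rate", self.null_rate),
                           ("multiallelic_rate", self.multiallelic_rate),
                           ("het_rate", self.het_rate),
                           ("low_conf_rate", self.low_conf_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.planted) > self.n_variants:
            raise ValueError("more planted variants than variant slots")
        for p in self.planted:
            n_ref = len(self.strains) - len(p.alt_strains)
            if p.discord1 > len(p.alt_strains) or p.discord2 > n_ref:
                raise ValueError("planted discordance exceeds group size")
            if not set(p.alt_strains) <= set(self.strains):
                raise ValueError("planted alt_strains must be panel strains")


@dataclass
class SiteTruth:
    chrom: str
    pos: int
    rsid: str
    planted: bool
    encoded: np.ndarray  # per-strain {0,1,NULL} as the loader must encode it
    dropped: bool
    #: (thr1, thr2) -> compatible flag w.r.t. the truth groups
    verdicts: dict[tuple[int, int], bool] = field(default_factory=dict)
    impact: str | None = None


@dataclass
class TruthTable:
    spec: FixtureSpec
    sites: list[SiteTruth]
    qc_counts: dict[str, Counter]
    groups: tuple[tuple[str, ...], tuple[str, ...]] | None

    def compatible_positions(self, thr1: int, thr2: int) -> set[tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.sites
                if not s.dropped and s.verdicts.get((thr1, thr2))}

    def n_dropped(self) -> int:
        return sum(s.dropped for s in self.sites)


def _draw_positions(rng, layout, n) -> list[tuple[str, int]]:
    # proportional to chromosome length, sorted, unique per chromosome
    lengths = np.array([ln for _, ln in layout], dtype=float)
    counts = np.floor(lengths / lengths.sum() * n).astype(int)
    counts[0] += n - counts.sum()
    out = []
    for (chrom, length), k in zip(layout, counts):
        pos = set()
        while len(pos) < k:
            pos.update(int(p) for p in rng.integers(1, length + 1, size=k - len(pos)))
        out.extend((chrom, p) for p in sorted(pos))
    return out


def generate_vcf(spec: FixtureSpec, path) -> TruthTable:
    """Write a synthetic multi-sample VCF and return its truth table.

    Planted variants realize their discordance structure exactly and are
    exempt from noise; background genotypes are fair coin flips over {0,1}
    with noise classes applied per call at the spec's rates. Truth verdicts
    are evaluated against ``spec.truth_groups`` (default: the first planted
    split) for every threshold pair in THR_GRID.
    """
    rng = np.random.default_rng(spec.seed)
    strains = tuple(spec.strains)
    n_str = len(strains)
    explicit = [p for p in spec.planted if p.pos is not None]
    implicit = [p for p in spec.planted if p.pos is None]
    taken = {(p.chrom or spec.chrom_layout[0][0], p.pos) for p in explicit}
    positions = [cp for cp in _draw_positions(rng, spec.chrom_layout, spec.n_variants)
                 if cp not in taken]

    # assign planted variants to slots (fixed positions keep their own)
    n_background = len(positions)
    plant_at: dict[int, PlantedVariant] = {}
    for p in explicit:
        positions.append((p.chrom or spec.chrom_layout[0][0], p.pos))
        plant_at[len(positions) - 1] = p
    slots = (rng.choice(n_background, size=len(implicit), replace=False)
             if implicit else [])
    for p, slot in zip(implicit, slots):
        plant_at[int(slot)] = p

    groups = spec.truth_groups
    if groups is None and spec.planted:
        alt = spec.planted[0].alt_strains
        groups = (tuple(alt), tuple(s for s in strains if s not in alt))

    order = sorted(range(len(positions)),
                   key=lambda i: (_chrom_key(positions[i][0]), positions[i][1]))

    header_csq = any(p.consequence for p in spec.planted)
    lines: list[str] = ["##fileformat=VCFv4.2"]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=FI,Number=1,Type=Integer,'
                 'Description="High confidence (1) or low confidence (0)">')
    if header_csq:
        lines.append('##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
                     'annotations. Format: Allele|Consequence|IMPACT|Gene">')
    for chrom, length in spec.chrom_layout:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains))

    qc: dict[str, Counter] = {s: Counter() for s in strains}
    sites: list[SiteTruth] = []
    rs_counter = 0

    for idx in order:
        chrom, pos = positions[idx]
        planted = plant_at.get(idx)
        ref, alt1, alt2 = (str(a) for a in rng.choice(_NUCS, size=4, replace=False)[:3])

        # intended homozygous alleles (allele index 0=ref, 1=alt1)
        if planted is not None:
            base = np.array([1 if s in planted.alt_strains else 0 for s in strains])
            alt_idx = [i for i, s in enumerate(strains) if s in planted.alt_strains]
            ref_idx = [i for i, s in enumerate(strains) if s not in planted.alt_strains]
            for i in list(rng.choice(alt_idx, size=planted.discord1, replace=False)):
                base[int(i)] = 0
            for i in list(rng.choice(ref_idx, size=planted.discord2, replace=False)):
                base[int(i)] = 1
        else:
            base = rng.integers(0, 2, size=n_str)

        gts, fis = [], []
        has_alt2 = False
        for j in range(n_str):
            gt, fi = (f"{base[j]}/{base[j]}", 1)
            if planted is None:
                u = float(rng.random())
                if u < spec.low_conf_rate:
                    fi = 0
                elif u < spec.low_conf_rate + spec.null_rate:
                    gt = "./."
                elif u < spec.low_conf_rate + spec.null_rate + spec.multiallelic_rate:
                    gt, has_alt2 = "2/2", True
                elif u < (spec.low_conf_rate + spec.null_rate
                          + spec.multiallelic_rate + spec.het_rate):
                    gt = "0/1"
            gts.append(gt)
            fis.append(fi)

        # truth classes exactly as the loader will classify them
        carriers = Counter()
        for gt in gts:
            if gt in ("1/1", "2/2"):
                carriers[int(gt[0])] += 1
        retained = 1 if carriers.get(1, 0) >= carriers.get(2, 0) else 2
        encoded = np.full(n_str, NULL, dtype=np.int8)
        for j, s in enumerate(strains):
            cls = classify_genotype(gts[j], retained, fis[j])
            encoded[j] = cls.encoded
            qc[s][cls.qc_label] += 1
        dropped = bool(np.all(encoded == NULL))

        rs_counter += 1
        rsid = planted.rsid if planted is not None and planted.rsid else f"sim{rs_counter}"
        info = "."
        if planted is not None and planted.consequence:
            gene = planted.gene_id or ""
            info = (f"CSQ={alt1}|{planted.consequence}|"
                    f"{impact_of(planted.consequence)}|{gene}")
        alt_field = alt1 if not has_alt2 else f"{alt1},{alt2}"
        calls = "\t".join(f"{g}:{f}" for g, f in zip(gts, fis))
        lines.append(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt_field}\t.\t.\t{info}\tGT:FI\t{calls}")

        truth = SiteTruth(chrom, pos, rsid, planted is not None, encoded, dropped,
                          impact=impact_of(planted.consequence)
                          if planted is not None and planted.consequence else None)
        if groups is not None and not dropped:
            i1 = [strains.index(s) for s in groups[0]]
            i2 = [strains.index(s) for s in groups[1]]
            for thr1, thr2 in THR_GRID:
                if thr1 >= len(i1) or thr2 >= len(i2):
                    continue
                truth.verdicts[(thr1, thr2)] = is_compatible(
                    encoded[i1], encoded[i2], thr1, thr2).compatible
        sites.append(truth)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return TruthTable(spec, sites, qc, groups)


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=gene:{g.gene_id};gene_id={g.gene_id};Name={g.gene_name}"
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# worked albinism example

ALBINO_STRAINS = ("A/J", "AKR/J", "BALB/cJ", "NOD/ShiLtJ")
NON_ALBINO_STRAINS = ("CBA/J", "C3H/HeJ", "DBA/2J", "C57BL/6NJ", "NZB/B1NJ")


def albinism_example() -> tuple[GenotypeMatrix, tuple[str, ...], tuple[str, ...]]:
    """Nine-strain albinism panel with six chr7 variants near the Tyr locus.

    Four strains are albino, five are not. Exactly one variant (rs31191169,
    the Tyr missense SNP at 7:87,493,043, C→G in albinos) has consistently
    different alleles between the groups; the variant immediately upstream
    segregates except for one non-albino strain, so it appears additionally
    when one discordant strain is allowed in the second group. The remaining
    four variants are discordant in at least two strains of the albino group
    under either allele assignment.

    Returns (matrix, albino_strains, non_albino_strains).
    """
    panel = StrainPanel(ALBINO_STRAINS + NON_ALBINO_STRAINS)
    tyr = "ENSMUSG00000004651"

    def rec(pos, rsid, ref, alt, alb, oth, consequences):
        return VariantRecord("7", pos, rsid, ref, alt,
                             np.array(alb + oth, dtype=np.int8), consequences)

    def ann(term, gene=None):
        from .genotype_store import ConsequenceAnnotation
        return [ConsequenceAnnotation(term, impact_of(term), gene)]

    records = [
        rec(87_100_000, "sim_a", "T", "A", [0, 0, 1, 1], [0, 1, 0, 1, 0],
            ann("intergenic_variant")),
        rec(87_200_000, "sim_b", "G", "C", [1, 0, 1, 0], [1, 1, 0, 0, 1],
            ann("upstream_gene_variant", tyr)),
        rec(87_400_000, "sim_c", "A", "G", [1, 1, 1, 1], [0, 0, 0, 0, 1],
            ann("intron_variant", tyr)),
        rec(87_493_043, "rs31191169", "C", "G", [1, 1, 1, 1], [0, 0, 0, 0, 0],
            ann("missense_variant", tyr)),
        rec(87_550_000, "sim_d", "C", "T", [0, 1, 0, 1], [1, 1, 1, 0, 0],
            ann("intron_variant", tyr)),
        rec(87_600_000, "sim_e", "T", "G", [1, 1, 0, 0], [1, 0, 1, 0, 1],
            ann("downstream_gene_variant", tyr)),
    ]
    return GenotypeMatrix(panel, records), ALBINO_STRAINS, NON_ALBINO_STRAINS


# ---------------------------------------------------------------------------
# expression fixtures

@dataclass(frozen=True)
class PlantedEqtl:
    """A transcript whose expression is bimodal over a cis variant's alleles."""

    transcript_id: str
    chrom: str
    tss: int
    alt_strains: tuple[str, ...]
    separation: float
    noise_sd: float = 1.0
    gene_id: str | None = None


def generate_expression(
    strains,
    planted_eqtls: list[PlantedEqtl],
    mice_per_strain: int = 2,
    base: float = 200.0,
    seed: int = 0,
):
    """Simulate per-mouse expression for planted cis effects.

    Mice of strains carrying the alternative allele draw from
    N(base + separation, noise_sd), all others from N(base, noise_sd); two
    mice per strain by default. Values are floored at 0 (intensity scale).
    Returns (ExpressionTable, truth) where truth maps transcript_id to the
    intended alternative-carrier strain set.
    """
    from .trait_tools import ExpressionTable

    rng = np.random.default_rng(seed)
    strains = tuple(strains)
    mice = [f"{s}#{i + 1}" for s in strains for i in range(mice_per_strain)]
    mouse_strain = pd.Series({m: m.split("#")[0] for m in mice})

    rows, meta_rows, truth = {}, [], {}
    for eq in planted_eqtls:
        mean = {s: base + (eq.separation if s in eq.alt_strains else 0.0) for s in strains}
        vals = [max(0.0, rng.normal(mean[mouse_strain[m]], eq.noise_sd)) for m in mice]
        rows[eq.transcript_id] = vals
        meta_rows.append({"transcript_id": eq.transcript_id,
                          "gene_id": eq.gene_id or eq.transcript_id,
                          "chrom": eq.chrom, "tss": eq.tss})
        truth[eq.transcript_id] = frozenset(eq.alt_strains)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=mice)
    meta = pd.DataFrame(meta_rows).set_index("transcript_id")
    return ExpressionTable(values, mouse_strain, meta), truth


@dataclass
class EqtlCohort:
    """A matched genotype + expression cohort with per-transcript causal truth."""

    matrix: GenotypeMatrix
    table: "object"  # ExpressionTable
    vcf_truth: TruthTable
    causal: dict[str, tuple[str, int]]  # transcript_id -> (chrom, pos)
    alt_strains: dict[str, frozenset]


def eqtl_cohort(
    out_dir,
    n_strains: int = 20,
    n_transcripts: int = 200,
    n_background: int = 2_000,
    mice_per_strain: int = 2,
    separation: float = 10.0,
    noise_sd: float = 1.0,
    window: int = 1_000_000,
    seed: int = 0,
) -> EqtlCohort:
    """Build a synthetic cohort for cis-scan studies and load it end to end.

    Per transcript a causal variant is planted that fully segregates with a
    random strain split (group sizes 5..n−5) and sits within ``window`` of
    the transcript's TSS; expression separates the two allele groups by
    ``separation`` (in units of noise_sd when noise_sd=1). The VCF is
    written to ``out_dir`` and reloaded through the standard loader.
    """
    from pathlib import Path

    from .genotype_store import load_vcf

    rng = np.random.default_rng(seed)
    strains = tuple(f"STR{i:02d}" for i in range(1, n_strains + 1))
    layout = (("1", 10_000_000), ("2", 10_000_000))

    planted, eqtls = [], []
    used_pos = set()
    for t in range(n_transcripts):
        tid = f"TX{t:04d}"
        chrom, length = layout[t % len(layout)]
        tss = int(rng.integers(window + 1, length - window))
        while True:
            pos = int(tss + rng.integers(-window, window + 1))
            if (chrom, pos) not in used_pos and pos >= 1:
                used_pos.add((chrom, pos))
                break
        k = int(rng.integers(5, n_strains - 4))
        alt = tuple(sorted(str(s) for s in rng.choice(strains, size=k, replace=False)))
        planted.append(PlantedVariant(alt_strains=alt, chrom=chrom, pos=pos))
        eqtls.append(PlantedEqtl(tid, chrom, tss, alt, separation, noise_sd))

    spec = FixtureSpec(strains=strains, n_variants=n_background,
                       planted=tuple(planted), chrom_layout=layout, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "cohort.vcf"
    truth = generate_vcf(spec, vcf_path)
    matrix = load_vcf(vcf_path, StrainPanel(strains))
    table, alt_truth = generate_expression(strains, eqtls, mice_per_strain, seed=seed + 1)
    causal = {eq.transcript_id: (eq.chrom, planted[i].pos)
              for i, eq in enumerate(eqtls)}
    return EqtlCohort(matrix, table, truth, causal,
                      {k: frozenset(v) for k, v in alt_truth.items()})
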