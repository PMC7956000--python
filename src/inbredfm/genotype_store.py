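"""Genotype matrix construction from multi-sample VCFs of inbred mouse strains.

Inbred strains are homozygous by design, so every usable genotype collapses to
one of two states: homozygous reference (encoded 0) or homozygous for the
retained alternative allele (encoded 1). Everything else — low-confidence
calls, missing calls, heterozygous calls, and calls involving an allele other
than the reference or the most frequent alternative — carries no usable
evidence and is encoded NULL. Sites where every strain is NULL are dropped.

Classification follows a fixed precedence: low confidence, missing,
multiallelic, homozygous, heterozygous; a call is assigned to the FIRST
matching class. The per-genotype confidence flag defaults to the Sanger Mouse
Genomes Project "FI" FORMAT key (value 0 = low confidence); VCFs without the
key are treated as fully confident.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .impacts import impact_of

logger = logging.getLogger(__name__)

#: Sentinel for NULL genotypes in the int8 genotype vectors.
NULL: int = -1

#: Mouse autosome names (GRCm38 convention, unprefixed).
MOUSE_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))

#: Default per-genotype confidence FORMAT key (Sanger MGP convention).
CONFIDENCE_KEY = "FI"


class GenotypeParseError(ValueError):
    """A genotype string could not be parsed; names the variant and strain."""


class GenotypeClass(enum.Enum):
    LOW_CONFIDENCE = "low_confidence"
    MISSING = "missing"
    MULTIALLELIC = "multiallelic"
    HOMOZYGOUS_REF = "homozygous_ref"
    HOMOZYGOUS_ALT = "homozygous_alt"
    HETEROZYGOUS = "heterozygous"

    @property
    def encoded(self) -> int:
        """Encoded genotype value: 0, 1 or NULL."""
        if self is GenotypeClass.HOMOZYGOUS_REF:
            return 0
        if self is GenotypeClass.HOMOZYGOUS_ALT:
            return 1
        return NULL

    @property
    def qc_label(self) -> str:
        """Label used in QC summaries (the two homozygous classes share one)."""
        if self in (GenotypeClass.HOMOZYGOUS_REF, GenotypeClass.HOMOZYGOUS_ALT):
            return "homozygous"
        return "low confidence" if self is GenotypeClass.LOW_CONFIDENCE else self.value


QC_CLASSES = ("homozygous", "low confidence", "missing", "multiallelic", "heterozygous")


@dataclass(frozen=True)
class StrainPanel:
    """Ordered panel of inbred strains, optionally naming the assembly strain.

    The reference strain (C57BL/6J for GRCm38) by definition carries the
    reference allele at every site, so it may be listed in the panel without
    appearing as a VCF sample column; it is then assigned 0 everywhere.
    """

    strains: tuple[str, ...]
    reference_strain: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "strains", tuple(self.strains))
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain identifiers must be unique")

    def __len__(self) -> int:
        return len(self.strains)

    def index(self, strain: str) -> int:
        return self.strains.index(strain)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    consequence_term: str
    impact: str
    gene_id: str | None = None


@dataclass
class VariantRecord:
    """One encoded SNV: position, alleles and the per-strain {0,1,NULL} vector."""

    chrom: str
    pos: int  # 1-based
    rsid: str
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # int8, aligned with the panel's strain order
    consequences: list[ConsequenceAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass
class GenotypeMatrix:
    """Variants × strains table of encoded genotypes, sorted by (chrom, pos)."""

    panel: StrainPanel
    records: list[VariantRecord]
    #: per-strain Counter over QC class labels, tallied at load (pre-drop)
    qc_class_counts: dict[str, Counter] = field(default_factory=dict)
    n_skipped_non_snv: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def strain_genotypes(self, strains) -> np.ndarray:
        """Genotype submatrix (variants × given strains); the reference strain
        is all-zero when absent from the stored vectors is not possible here —
        vectors always cover the full panel, so this is a simple column pick."""
        idx = [self.panel.index(s) for s in strains]
        if not self.records:
            return np.empty((0, len(idx)), dtype=np.int8)
        return np.stack([r.genotypes[idx] for r in self.records])

    def subset_region(self, chrom: str, start: int, end: int) -> list[VariantRecord]:
        """Records in the closed 1-based interval [start, end] on chrom."""
        return [r for r in self.records if r.chrom == chrom and start <= r.pos <= end]

    def to_vcf(self, path) -> None:
        """Export encoded genotypes as a plain-text VCF (0→0/0, 1→1/1, NULL→./.)."""
        chroms = sorted({r.chrom for r in self.records}, key=_chrom_key)
        samples = [s for s in self.panel.strains if s != self.panel.reference_strain]
        sample_idx = [self.panel.index(s) for s in samples]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            gt_str = {0: "0/0", 1: "1/1", NULL: "./."}
            for r in self.records:
                calls = "\t".join(gt_str[int(r.genotypes[i])] for i in sample_idx)
                fh.write(f"{r.chrom}\t{r.pos}\t{r.rsid or '.'}\t{r.ref_allele}\t"
                         f"{r.alt_allele}\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# region handling

@dataclass(frozen=True)
class Region:
    """Closed 1-based interval ``chrom:start-end``; start/end may be open-ended."""

    chrom: str
    start: int = 1
    end: int = 2**62

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def parse_region(text: str) -> Region:
    """Parse ``chrom`` or ``chrom:start-end`` (commas in numbers allowed)."""
    if ":" not in text:
        return Region(text)
    chrom, span = text.split(":", 1)
    start_s, _, end_s = span.partition("-")
    start = int(start_s.replace(",", ""))
    end = int(end_s.replace(",", "")) if end_s else 2**62
    if start > end:
        raise ValueError(f"region start exceeds end: {text!r}")
    return Region(chrom, start, end)


# ---------------------------------------------------------------------------
# classification and encoding

def _parse_gt_string(gt: str, *, variant: str = "?", strain: str = "?") -> tuple:
    alleles = []
    for tok in gt.replace("|", "/").split("/"):
        if tok == ".":
            alleles.append(None)
        else:
            try:
                alleles.append(int(tok))
            except ValueError:
                raise GenotypeParseError(
                    f"malformed genotype {gt!r} for strain {strain} at {variant}"
                ) from None
    return tuple(alleles)


def classify_genotype(
    gt,
    retained_alt_index: int,
    confidence: int | None = None,
    *,
    variant: str = "?",
    strain: str = "?",
) -> GenotypeClass:
    """Classify one genotype call by the fixed precedence order.

    Parameters
    ----------
    gt
        Allele tuple as pysam reports it (ints and/or None), or a raw
        genotype string such as ``"0/1"`` or ``"./."``.
    retained_alt_index
        1-based allele index of the retained (most frequent) alternative.
    confidence
        Per-genotype confidence flag value; 0 marks low confidence, anything
        else (including None/absent) is treated as confident.
    """
    if isinstance(gt, str):
        gt = _parse_gt_string(gt, variant=variant, strain=strain)
    if confidence == 0:
        return GenotypeClass.LOW_CONFIDENCE
    if len(gt) == 0 or any(a is None for a in gt):
        return GenotypeClass.MISSING
    if any(a not in (0, retained_alt_index) for a in gt):
        return GenotypeClass.MULTIALLELIC
    if all(a == 0 for a in gt):
        return GenotypeClass.HOMOZYGOUS_REF
    if all(a == retained_alt_index for a in gt):
        return GenotypeClass.HOMOZYGOUS_ALT
    return GenotypeClass.HETEROZYGOUS


_SNV_ALLELES = frozenset("ACGT")


def _is_snv(ref: str, alts) -> bool:
    if alts is None:
        return False
    return ref in _SNV_ALLELES and all(a in _SNV_ALLELES for a in alts)


def _sample_confidence(sample, confidence_key: str):
    try:
        v = sample[confidence_key]
    except KeyError:
        return None
    if isinstance(v, tuple):
        v = v[0] if v else None
    return v


def encode_site(
    vcf_record,
    panel: StrainPanel,
    confidence_key: str = CONFIDENCE_KEY,
    csq_fields: list[str] | None = None,
    collect: dict[str, Counter] | None = None,
) -> VariantRecord | None:
    """Encode one pysam VCF record; returns None when every strain is NULL.

    The retained alternative is the ALT allele carried homozygously by the
    largest number of panel strains (ties go to the first-listed ALT). A
    panel reference strain absent from the sample columns encodes 0.
    """
    alts = vcf_record.alts or ()
    vid = f"{vcf_record.chrom}:{vcf_record.pos}"
    sample_names = set(vcf_record.samples.keys())
    present = [s for s in panel.strains if s in sample_names]

    # choose the retained alternative by homozygous-carrier count (GT only)
    carriers = [0] * len(alts)
    for s in present:
        gt = vcf_record.samples[s].get("GT") or ()
        if gt and all(a is not None for a in gt) and len(set(gt)) == 1 and gt[0] >= 1:
            if gt[0] - 1 < len(alts):
                carriers[gt[0] - 1] += 1
    retained = 1 + max(range(len(alts)), key=lambda i: carriers[i]) if alts else 1

    genotypes = np.full(len(panel), NULL, dtype=np.int8)
    for i, strain in enumerate(panel.strains):
        if strain not in sample_names:
            if strain == panel.reference_strain:
                genotypes[i] = 0
                if collect is not None:
                    collect.setdefault(strain, Counter())["homozygous"] += 1
            continue
        sample = vcf_record.samples[strain]
        cls = classify_genotype(
            sample.get("GT") or (),
            retained,
            _sample_confidence(sample, confidence_key),
            variant=vid,
            strain=strain,
        )
        genotypes[i] = cls.encoded
        if collect is not None:
            collect.setdefault(strain, Counter())[cls.qc_label] += 1

    if np.all(genotypes == NULL):
        return None

    consequences: list[ConsequenceAnnotation] = []
    if csq_fields is not None and "CSQ" in (vcf_record.info or {}):
        raw = vcf_record.info["CSQ"]
        if isinstance(raw, str):
            raw = (raw,)
        consequences = parse_consequences(",".join(raw), csq_fields)

    return VariantRecord(
        chrom=vcf_record.chrom,
        pos=vcf_record.pos,
        rsid=vcf_record.id or "",
        ref_allele=vcf_record.ref,
        alt_allele=alts[retained - 1] if alts else "",
        genotypes=genotypes,
        consequences=consequences,
    )


def parse_consequences(csq_info: str, format_spec: list[str]) -> list[ConsequenceAnnotation]:
    """Parse a VEP CSQ string into annotations, one per transcript-consequence.

    ``format_spec`` lists the pipe-separated field names (from the VCF
    header). Terms joined by "&" are split and mapped individually. When an
    IMPACT field is absent the impact is derived from the bundled
    consequence→impact table.
    """
    if not csq_info:
        return []
    lower = [f.lower() for f in format_spec]
    i_cons = lower.index("consequence") if "consequence" in lower else None
    i_imp = lower.index("impact") if "impact" in lower else None
    i_gene = lower.index("gene") if "gene" in lower else None
    out: list[ConsequenceAnnotation] = []
    for entry in csq_info.split(","):
        if not entry:
            continue
        fields = entry.split("|")

        def get(i):
            return fields[i] if i is not None and i < len(fields) and fields[i] else None

        terms = (get(i_cons) or "").split("&")
        gene = get(i_gene)
        declared = get(i_imp)
        for term in terms:
            if not term:
                continue
            out.append(ConsequenceAnnotation(term, declared or impact_of(term), gene))
    return out


def _csq_format_from_header(header) -> list[str] | None:
    if "CSQ" not in header.info:
        return None
    desc = header.info["CSQ"].description or ""
    if "Format:" in desc:
        return desc.split("Format:", 1)[1].strip().strip('"').split("|")
    return None


def load_vcf(
    path,
    panel: StrainPanel,
    regions=None,
    autosomes_only: bool = False,
    autosomes=MOUSE_AUTOSOMES,
    confidence_key: str = CONFIDENCE_KEY,
) -> GenotypeMatrix:
    """Load a VCF into an encoded, sorted GenotypeMatrix.

    Non-SNV records are skipped (counted). All-NULL records are dropped.
    ``regions`` may be Region objects or ``chrom:start-end`` strings (closed
    1-based intervals). Raises on panel strains missing from the VCF header
    and on unsorted input.
    """
    if regions is not None:
        regions = [r if isinstance(r, Region) else parse_region(r) for r in regions]
    vf = pysam.VariantFile(str(path))
    samples = set(vf.header.samples)
    missing = [s for s in panel.strains
               if s not in samples and s != panel.reference_strain]
    if missing:
        raise ValueError(f"panel strains missing from VCF: {', '.join(missing)}")
    csq_fields = _csq_format_from_header(vf.header)

    records: list[VariantRecord] = []
    qc: dict[str, Counter] = {}
    n_non_snv = 0
    last_chrom, last_pos = None, 0
    seen_chroms: set[str] = set()
    for rec in vf:
        if rec.chrom != last_chrom:
            if rec.chrom in seen_chroms:
                raise ValueError(f"unsorted VCF: chromosome {rec.chrom} revisited")
            seen_chroms.add(rec.chrom)
            last_chrom, last_pos = rec.chrom, 0
        elif rec.pos < last_pos:
            raise ValueError(f"unsorted VCF at {rec.chrom}:{rec.pos}")
        last_pos = rec.pos
        if autosomes_only and rec.chrom.removeprefix("chr") not in autosomes:
            continue
        if regions is not None and not any(r.contains(rec.chrom, rec.pos) for r in regions):
            continue
        if not _is_snv(rec.ref, rec.alts):
            n_non_snv += 1
            continue
        encoded = encode_site(rec, panel, confidence_key, csq_fields, collect=qc)
        if encoded is not None:
            records.append(encoded)
    if n_non_snv:
        logger.info("skipped %d non-SNV records", n_non_snv)
    records.sort(key=lambda r: (_chrom_key(r.chrom), r.pos))
    return GenotypeMatrix(panel, records, qc, n_non_snv)


# ---------------------------------------------------------------------------
# QC summaries

def strain_qc_summary(matrix: GenotypeMatrix, raw_class_counts=None) -> pd.DataFrame:
    """Per-strain genotype-class counts tallied over all scanned SNV sites.

    Counts are collected before all-NULL records are dropped, so per strain
    they sum to the number of SNV sites scanned. Returns a tidy frame with
    columns (strain, class, count).
    """
    counts = raw_class_counts if raw_class_counts is not None else matrix.qc_class_counts
    rows = [
        {"strain": strain, "class": cls, "count": counts.get(strain, Counter()).get(cls, 0)}
        for strain in matrix.panel.strains
        for cls in QC_CLASSES
    ]
    return pd.DataFrame(rows)


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA of strains over sites complete (no NULL) across the panel.

    Columns are mean-centered 0/1 genotypes, no scaling. Coordinates are
    reproducible up to a sign flip per component. Returns a strains ×
    components frame (PC1, PC2, ...).
    """
    from sklearn.decomposition import PCA

    complete = [r.genotypes for r in matrix.records if not np.any(r.genotypes == NULL)]
    if len(complete) < n_components:
        raise ValueError(
            f"only {len(complete)} complete sites for {n_components} components"
        )
    X = np.stack(complete).T.astype(float)  # strains × sites
    coords = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    return pd.DataFrame(
        coords,
        index=list(matrix.panel.strains),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
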