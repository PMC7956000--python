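"""Locus merging and gene annotation.

Compatible variants frequently cluster into haplotype blocks; merging
consecutive compatible variants separated by no more than a gap limit yields
candidate loci worth following up experimentally. Gene annotation intersects
variants or loci with gene models read from local GFF3/GTF files, optionally
extending gene spans by a flanking distance. All coordinates are 1-based
closed intervals (VCF/GFF convention); strand is used only to derive the
transcription start site, never for overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from .genotype_store import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    """Maximal run of compatible variants on one chromosome within max_gap."""

    chrom: str
    start: int
    end: int
    variants: list[VariantRecord] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        """Transcription start site: start on the + strand, end on the − strand."""
        return self.end if self.strand == "-" else self.start


def merge_loci(variants: list[VariantRecord], max_gap: int = 1_000_000) -> list[Locus]:
    """Merge position-sorted variants into loci by a single linear pass.

    A new locus starts at each chromosome change or whenever the distance to
    the previous variant exceeds ``max_gap``. Every variant lands in exactly
    one locus; per chromosome, loci are separated by more than ``max_gap``.
    """
    loci: list[Locus] = []
    prev_chrom, prev_pos = None, 0
    for v in variants:
        if v.chrom == prev_chrom and v.pos < prev_pos:
            raise ValueError("variants must be sorted by (chrom, pos)")
        if v.chrom != prev_chrom or v.pos - prev_pos > max_gap:
            loci.append(Locus(v.chrom, v.pos, v.pos, [v]))
        else:
            loci[-1].end = v.pos
            loci[-1].variants.append(v)
        prev_chrom, prev_pos = v.chrom, v.pos
    return loci


def _attr(feature, *keys) -> str | None:
    for k in keys:
        if k in feature.attributes:
            vals = feature.attributes[k]
            if vals:
                return vals[0]
    return None


def read_gff(path, gene_featuretypes=("gene",)) -> list[GeneModel]:
    """Read gene-level features from a GFF3 or GTF file into GeneModels.

    Coordinates stay 1-based inclusive as in the file. Records lacking a
    gene identifier attribute are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for ftype in gene_featuretypes:
        for feat in db.features_of_type(ftype):
            gene_id = _attr(feat, "gene_id", "ID", "Name")
            if gene_id is None:
                logger.warning("skipping %s feature at %s:%d-%d without gene identifier",
                               ftype, feat.seqid, feat.start, feat.end)
                continue
            gene_id = gene_id.removeprefix("gene:")
            name = _attr(feat, "gene_name", "Name") or gene_id
            genes.append(GeneModel(gene_id, name, feat.seqid, feat.start, feat.end,
                                   feat.strand or "+"))
    return genes


def _item_span(item) -> tuple[str, int, int]:
    if isinstance(item, Locus):
        return item.chrom, item.start, item.end
    return item.chrom, item.pos, item.pos


def annotate_genes(items, genes: list[GeneModel], flank: int = 0) -> list[tuple]:
    """Attach overlapping genes to variants or loci.

    A gene overlaps an item when its flank-extended closed interval
    [start − flank, end + flank] intersects the item's position or span.
    Returns (item, [GeneModel, ...]) pairs; gene lists are ordered by
    (chrom, start, gene_id) and empty when nothing overlaps.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # closed 1-based interval -> half-open for the tree
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - flank, g.end + flank + 1, g
        )
    out = []
    for item in items:
        chrom, start, end = _item_span(item)
        hits = trees[chrom].overlap(start, end + 1) if chrom in trees else ()
        found = sorted((h.data for h in hits), key=lambda g: (g.chrom, g.start, g.gene_id))
        out.append((item, found))
    return out


def loci_to_bed(loci: list[Locus], path) -> None:
    """Write loci as BED6 (0-based half-open), name = variant count."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t"
                     f"n={loc.n_variants}\t{loc.n_variants}\t.\n")
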