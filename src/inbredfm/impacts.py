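"""Sequence-ontology consequence terms and their Ensembl Variation impact categories.

The severity categories HIGH, MODERATE, LOW and MODIFIER follow the Ensembl
Variation calculated-variant-consequences table. Terms not in the table are
treated as MODIFIER (the catch-all category) with a logged warning.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"

IMPACTS = (HIGH, MODERATE, LOW, MODIFIER)

# Ordered most to least severe, for per-variant max-impact summaries.
_SEVERITY_RANK = {HIGH: 0, MODERATE: 1, LOW: 2, MODIFIER: 3}

CONSEQUENCE_IMPACT: dict[str, str] = {
    # HIGH
    "transcript_ablation": HIGH,
    "splice_acceptor_variant": HIGH,
    "splice_donor_variant": HIGH,
    "stop_gained": HIGH,
    "frameshift_variant": HIGH,
    "stop_lost": HIGH,
    "start_lost": HIGH,
    "transcript_amplification": HIGH,
    "feature_elongation": HIGH,
    "feature_truncation": HIGH,
    # MODERATE
    "inframe_insertion": MODERATE,
    "inframe_deletion": MODERATE,
    "missense_variant": MODERATE,
    "protein_altering_variant": MODERATE,
    # LOW
    "splice_donor_5th_base_variant": LOW,
    "splice_region_variant": LOW,
    "splice_donor_region_variant": LOW,
    "splice_polypyrimidine_tract_variant": LOW,
    "incomplete_terminal_codon_variant": LOW,
    "start_retained_variant": LOW,
    "stop_retained_variant": LOW,
    "synonymous_variant": LOW,
    # MODIFIER
    "coding_sequence_variant": MODIFIER,
    "mature_miRNA_variant": MODIFIER,
    "5_prime_UTR_variant": MODIFIER,
    "3_prime_UTR_variant": MODIFIER,
    "non_coding_transcript_exon_variant": MODIFIER,
    "intron_variant": MODIFIER,
    "NMD_transcript_variant": MODIFIER,
    "non_coding_transcript_variant": MODIFIER,
    "coding_transcript_variant": MODIFIER,
    "upstream_gene_variant": MODIFIER,
    "downstream_gene_variant": MODIFIER,
    "TFBS_ablation": MODIFIER,
    "TFBS_amplification": MODIFIER,
    "TF_binding_site_variant": MODIFIER,
    "regulatory_region_ablation": MODIFIER,
    "regulatory_region_amplification": MODIFIER,
    "regulatory_region_variant": MODIFIER,
    "intergenic_variant": MODIFIER,
    "sequence_variant": MODIFIER,
}


def impact_of(consequence_term: str) -> str:
    """Impact category for a consequence term; unknown terms fall back to MODIFIER."""
    try:
        return CONSEQUENCE_IMPACT[consequence_term]
    except KeyError:
        logger.warning("unknown consequence term %r; assuming MODIFIER", consequence_term)
        return MODIFIER


def max_impact(impacts) -> str | None:
    """Most severe impact among ``impacts``; None when empty."""
    impacts = list(impacts)
    if not impacts:
        return None
    return min(impacts, key=lambda i: _SEVERITY_RANK[i])
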