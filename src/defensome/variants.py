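"""High-frequency variant filtering, classification and per-family
enrichment.

The analyzed region of a gene is its body plus the 200 bp immediately
upstream of the start codon (strand-aware).  A variant is retained as
"high-frequency" when its allele frequency is >= 25% and it is supported
by >= 10 reads (both inclusive).  SNPs inside the gene body are typed as
synonymous/nonsynonymous against the reference CDS under the standard
genetic code when the CDS is available.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import EnrichmentCell, GeneRecord, GeneVariantSummary, VariantRecord

UPSTREAM_BP = 200

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# standard genetic code (NCBI table 1); used for single-substitution typing
CODON_TABLE: Dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    CODON_TABLE.update(table.forward_table)
    for stop in table.stop_codons:
        CODON_TABLE[stop] = "*"


_build_codon_table()


def filter_high_frequency(
    variants: Sequence[VariantRecord],
    min_freq: float = 0.25,
    min_reads: int = 10,
) -> List[VariantRecord]:
    """Keep variants with allele_frequency >= min_freq AND
    supporting_reads >= min_reads (boundaries inclusive)."""
    return [
        v
        for v in variants
        if v.allele_frequency >= min_freq and v.supporting_reads >= min_reads
    ]


def upstream_window(gene: GeneRecord, upstream_bp: int = UPSTREAM_BP) -> Tuple[int, int]:
    """Contig coordinates (1-based inclusive) of the strand-aware window
    upstream of the start codon."""
    if gene.strand == "+":
        return max(1, gene.start - upstream_bp), gene.start - 1
    return gene.end + 1, gene.end + upstream_bp


def classify_variant(
    variant: VariantRecord,
    gene: GeneRecord,
    cds_sequence: Optional[str] = None,
    ref_base: Optional[str] = None,
    alt_base: Optional[str] = None,
    upstream_bp: int = UPSTREAM_BP,
) -> VariantRecord:
    """Assign region (gene_body vs 200-bp upstream, strand-aware) and,
    when the CDS is given, the synonymous/nonsynonymous type of a SNP.

    ``variant.position`` is a contig coordinate.  ``cds_sequence`` is the
    coding strand sequence of the gene; for minus-strand genes the variant
    alleles are complemented before codon substitution.  Indels keep
    var_type='indel'; SNPs without a CDS become 'SNP_unclassified'.
    """
    pos = variant.position
    up_lo, up_hi = upstream_window(gene, upstream_bp)
    if gene.start <= pos <= gene.end:
        region = "gene_body"
    elif up_lo <= pos <= up_hi:
        region = "upstream"
    else:
        raise ValueError(
            f"variant {variant.gene_id}@{pos} outside gene body and "
            f"{upstream_bp} bp upstream window of gene {gene.gene_id}"
        )

    var_type = variant.var_type
    if var_type == "indel":
        return replace(variant, region=region)
    if region == "upstream" or cds_sequence is None or ref_base is None or alt_base is None:
        new_type = var_type if var_type != "indel" else "indel"
        if region == "upstream" or cds_sequence is None:
            new_type = "SNP_unclassified" if var_type.startswith("SNP") else var_type
        return replace(variant, region=region, var_type=new_type)

    # position within the coding sequence, 0-based, strand aware
    if gene.strand == "+":
        cds_pos = pos - gene.start
        ref, alt = ref_base.upper(), alt_base.upper()
    else:
        cds_pos = gene.end - pos
        ref = ref_base.upper().translate(_COMPLEMENT)
        alt = alt_base.upper().translate(_COMPLEMENT)
    if cds_pos >= len(cds_sequence):
        raise ValueError(
            f"variant {variant.gene_id}@{pos}: CDS shorter than gene span"
        )
    codon_i = cds_pos // 3
    offset = cds_pos % 3
    codon = cds_sequence[3 * codon_i : 3 * codon_i + 3].upper()
    if len(codon) < 3:
        return replace(variant, region=region, var_type="SNP_unclassified")
    if codon[offset] != ref:
        raise ValueError(
            f"variant {variant.gene_id}@{pos}: reference allele {ref!r} does not "
            f"match CDS base {codon[offset]!r}"
        )
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = CODON_TABLE.get(codon)
    aa_alt = CODON_TABLE.get(mutated)
    if aa_ref is None or aa_alt is None:
        return replace(variant, region=region, var_type="SNP_unclassified")
    new_type = "SNP_synonymous" if aa_ref == aa_alt else "SNP_nonsynonymous"
    return replace(variant, region=region, var_type=new_type)


def summarize_gene_variants(
    gene: GeneRecord,
    family: str,
    variants: Sequence[VariantRecord],
    upstream_bp: int = UPSTREAM_BP,
) -> GeneVariantSummary:
    """Summarize retained variants of one gene: counts, density over the
    analyzed length (gene + upstream window), and type/region fractions."""
    summary = GeneVariantSummary(
        gene_id=gene.gene_id,
        family=family,
        analyzed_length_bp=gene.length + upstream_bp,
    )
    n = len(variants)
    if n == 0:
        return summary
    type_counts: Dict[str, int] = defaultdict(int)
    region_counts: Dict[str, int] = defaultdict(int)
    for v in variants:
        if v.var_type == "indel":
            summary.n_indel += 1
        else:
            summary.n_snp += 1
        type_key = (
            "indel"
            if v.var_type == "indel"
            else v.var_type.replace("SNP_", "")
        )
        type_counts[type_key] += 1
        region_counts[v.region] += 1
    summary.has_high_frequency_variant = True
    summary.type_fractions = {k: c / n for k, c in sorted(type_counts.items())}
    summary.region_fractions = {k: c / n for k, c in sorted(region_counts.items())}
    return summary


def family_variant_oe(
    summaries: Sequence[GeneVariantSummary],
    min_genes_per_family: int = 10,
    highlight_threshold: float = 1.5,
) -> dict:
    """Per-family O/E of genes carrying high-frequency variants.

    E_f = N_f * (overall fraction of analyzed genes flagged); families
    with fewer than ``min_genes_per_family`` analyzed genes are excluded.
    Families with O/E >= ``highlight_threshold`` are flagged.  A global
    two-sided chi-square is computed over included families with E >= 1.
    """
    fam_total: Dict[str, int] = defaultdict(int)
    fam_flagged: Dict[str, int] = defaultdict(int)
    for s in summaries:
        fam_total[s.family] += 1
        if s.has_high_frequency_variant:
            fam_flagged[s.family] += 1

    included = {f for f, n in fam_total.items() if n >= min_genes_per_family}
    if not included:
        raise ValueError("no family passes the minimum gene count")
    n_all = sum(fam_total[f] for f in included)
    n_flagged = sum(fam_flagged.get(f, 0) for f in included)
    overall = n_flagged / n_all if n_all else 0.0

    cells: List[EnrichmentCell] = []
    stat = 0.0
    n_tested = 0
    for fam in sorted(included):
        obs = fam_flagged.get(fam, 0)
        exp = fam_total[fam] * overall
        oe = obs / exp if exp > 0 else float("nan")
        contrib = (obs - exp) ** 2 / exp if exp > 0 else 0.0
        if exp >= 1.0:
            stat += contrib
            n_tested += 1
        cells.append(
            EnrichmentCell(
                family=fam,
                category="high_frequency",
                observed=obs,
                expected=exp,
                oe=oe,
                chi2_contribution=contrib,
            )
        )
    dof = max(n_tested - 1, 1)
    p = float(stats.chi2.sf(stat, dof)) if overall > 0 else float("nan")
    highlighted = [c.family for c in cells if np.isfinite(c.oe) and c.oe >= highlight_threshold]
    return {
        "cells": cells,
        "overall_fraction": overall,
        "statistic": stat,
        "dof": dof,
        "p": p,
        "highlighted": highlighted,
        "excluded_families": sorted(set(fam_total) - included),
    }
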