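"""Defense-MGE colocalization and family-pair colocalization statistics.

Two enrichment views:

* family x MGE-context observed/expected (O/E) matrix under the
  independence expectation ``E[f, m] = N_f * N_.m / N_..`` with a global
  chi-square test over cells with expected >= 1;
* per unordered family pair, the odds ratio of colocalizing inside vs
  outside defense islands, over close gene pairs (<= ``pair_gap``
  intervening genes), excluding pairs whose genes belong to the same
  assembled system (which would otherwise inflate colocalization).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .islands import index_islands, odds_ratio_2x2
from .types import (
    DefenseAnnotation,
    DefenseSystem,
    EnrichmentCell,
    GeneRecord,
    Island,
    MGEInterval,
    PairAssociation,
)

CHROMOSOME = "chromosome"
UNKNOWN_FAMILY = "unknown"


def tag_mge_membership(
    genes: Sequence[GeneRecord],
    intervals: Sequence[MGEInterval],
    flank_bp: int = 0,
) -> Dict[str, str]:
    """Label each gene with the MGE class whose (flank-extended) interval
    it overlaps by >= 1 bp, else 'chromosome'.

    If a gene overlaps intervals of several classes (possible only via
    flanks once conflicts are filtered), the class with the largest
    overlap wins; ties break lexicographically.
    """
    by_contig: Dict[str, List[MGEInterval]] = defaultdict(list)
    for iv in intervals:
        by_contig[iv.contig_id].append(iv)

    labels: Dict[str, str] = {}
    for gene in genes:
        best: Optional[Tuple[int, str]] = None
        for iv in by_contig.get(gene.contig_id, ()):
            lo = iv.start - flank_bp
            hi = iv.end + flank_bp
            overlap = min(gene.end, hi) - max(gene.start, lo) + 1
            if overlap >= 1:
                key = (overlap, iv.mge_class)
                if best is None or overlap > best[0] or (
                    overlap == best[0] and iv.mge_class < best[1]
                ):
                    best = key
        labels[gene.gene_id] = best[1] if best else CHROMOSOME
    return labels


def mge_defense_density(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    intervals: Sequence[MGEInterval],
    size_bp: int,
    flank_bp: int = 0,
) -> Dict[str, float]:
    """Defense genes per kb in each context of one MAG.

    Context lengths: summed interval lengths per MGE class; chromosome =
    size_bp minus all MGE bp.  Contexts with zero length are omitted.
    """
    labels = tag_mge_membership(genes, intervals, flank_bp=flank_bp)
    defense_ids = {h.gene_id for h in hits}
    counts: Dict[str, int] = defaultdict(int)
    for g in genes:
        if g.gene_id in defense_ids:
            counts[labels[g.gene_id]] += 1

    context_bp: Dict[str, int] = defaultdict(int)
    for iv in intervals:
        context_bp[iv.mge_class] += iv.length
    chrom_bp = size_bp - sum(context_bp.values())
    if chrom_bp <= 0:
        raise ValueError(
            "chromosome length <= 0 after subtracting MGE spans; inconsistent annotation"
        )
    context_bp[CHROMOSOME] = chrom_bp

    return {
        ctx: counts.get(ctx, 0) / (bp / 1000.0)
        for ctx, bp in sorted(context_bp.items())
        if bp > 0
    }


# ---------------------------------------------------------------------------
# family x MGE O/E
# ---------------------------------------------------------------------------

def mge_family_oe(
    hits: Sequence[DefenseAnnotation],
    labels: Dict[str, str],
    min_expected: float = 1.0,
) -> dict:
    """O/E matrix of defense families across MGE contexts.

    Expected counts follow the independence margin over *all* defense
    genes: E[f, m] = N_f * (N_.m / N_..).  The chromosome context is part
    of the table so that row expectations sum to row totals.  A global
    two-sided chi-square goodness-of-fit is computed over cells with
    expected >= ``min_expected``; cells with observed 0 are reported with
    oe = 0 ("absent").
    """
    table: Dict[Tuple[str, str], int] = defaultdict(int)
    fam_tot: Dict[str, int] = defaultdict(int)
    cat_tot: Dict[str, int] = defaultdict(int)
    for hit in hits:
        cat = labels.get(hit.gene_id, CHROMOSOME)
        table[(hit.family, cat)] += 1
        fam_tot[hit.family] += 1
        cat_tot[cat] += 1
    grand = sum(fam_tot.values())
    if len(fam_tot) < 2 or len(cat_tot) < 2 or grand == 0:
        raise ValueError("need >= 2 families and >= 2 contexts with nonzero totals")

    cells: List[EnrichmentCell] = []
    stat = 0.0
    n_tested = 0
    for fam in sorted(fam_tot):
        for cat in sorted(cat_tot):
            obs = table.get((fam, cat), 0)
            exp = fam_tot[fam] * (cat_tot[cat] / grand)
            contrib = (obs - exp) ** 2 / exp if exp > 0 else 0.0
            if exp >= min_expected:
                stat += contrib
                n_tested += 1
            cells.append(
                EnrichmentCell(
                    family=fam,
                    category=cat,
                    observed=obs,
                    expected=exp,
                    oe=obs / exp if exp > 0 else float("nan"),
                    chi2_contribution=contrib,
                )
            )
    dof = (len(fam_tot) - 1) * (len(cat_tot) - 1)
    p = float(stats.chi2.sf(stat, dof)) if dof > 0 else float("nan")
    return {
        "cells": cells,
        "statistic": stat,
        "dof": dof,
        "p": p,
        "n_cells_tested": n_tested,
    }


# ---------------------------------------------------------------------------
# family-pair colocalization inside/outside islands
# ---------------------------------------------------------------------------

def enumerate_close_pairs(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    *,
    systems: Optional[Sequence[DefenseSystem]] = None,
    pair_gap: int = 5,
) -> List[Tuple[GeneRecord, GeneRecord, str, str]]:
    """All unordered defense-gene pairs on the same contig separated by
    <= pair_gap intervening genes, excluding pairs within one system."""
    system_of: Dict[str, str] = {}
    for sys in systems or ():
        for gid in sys.member_gene_ids:
            system_of[gid] = sys.system_id

    fam_of = {h.gene_id: h.family for h in hits}
    by_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    gene_index = {g.gene_id: g for g in genes}
    for hit in hits:
        g = gene_index[hit.gene_id]
        by_contig[g.contig_id].append(g)

    pairs = []
    for contig in sorted(by_contig):
        dgenes = sorted(by_contig[contig], key=lambda g: g.ordinal)
        for i, gi in enumerate(dgenes):
            for gj in dgenes[i + 1 :]:
                if gj.ordinal - gi.ordinal - 1 > pair_gap:
                    break
                si, sj = system_of.get(gi.gene_id), system_of.get(gj.gene_id)
                if si is not None and si == sj:
                    continue
                pairs.append((gi, gj, fam_of[gi.gene_id], fam_of[gj.gene_id]))
    return pairs


def family_pair_colocalization(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    islands: Sequence[Island],
    *,
    systems: Optional[Sequence[DefenseSystem]] = None,
    pair_gap: int = 5,
) -> List[PairAssociation]:
    """Odds ratio of each family pair colocalizing inside vs outside
    defense islands.

    A pair is 'inside' when both genes fall within the span of one
    island; pairs straddling an island boundary count as outside.  Pairs
    involving an 'unknown'-family gene stay in the totals but get no row.
    Raises when no outside pairs exist at all (OR undefined).
    """
    pairs = enumerate_close_pairs(genes, hits, systems=systems, pair_gap=pair_gap)
    by_contig = index_islands(islands)

    pair_counts: Dict[Tuple[str, str], List[int]] = defaultdict(lambda: [0, 0])
    total_in = total_out = 0
    for gi, gj, fa, fb in pairs:
        inside = any(
            isl.contains_ordinal(gi.ordinal) and isl.contains_ordinal(gj.ordinal)
            for isl in by_contig.get(gi.contig_id, ())
        )
        if inside:
            total_in += 1
        else:
            total_out += 1
        key = tuple(sorted((fa, fb)))
        pair_counts[key][0 if inside else 1] += 1

    if total_out == 0 and total_in > 0:
        raise ValueError("no outside pairs: odds ratios undefined")

    out: List[PairAssociation] = []
    for (fa, fb), (n_in, n_out) in sorted(pair_counts.items()):
        if UNKNOWN_FAMILY in (fa, fb):
            continue
        other_in = total_in - n_in
        other_out = total_out - n_out
        _, p = stats.fisher_exact(
            [[n_in, n_out], [other_in, other_out]], alternative="two-sided"
        )
        out.append(
            PairAssociation(
                family_a=fa,
                family_b=fb,
                pairs_in=n_in,
                pairs_out=n_out,
                other_pairs_in=other_in,
                other_pairs_out=other_out,
                odds_ratio=odds_ratio_2x2(n_in, n_out, other_in, other_out),
                fisher_p=float(p),
            )
        )
    return out
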