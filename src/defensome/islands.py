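"""Defense-island calling and island content statistics.

A defense island is a maximal array of defense units on one contig in
which consecutive units are separated by at most ``gap_max`` intervening
genes, with at least ``min_units`` units from at least ``min_families``
distinct defense families.  The counting unit is either individual
defense genes (default) or assembled defense systems (a system sits at
the ordinal of its first member gene).

The island span runs from the first to the last defense member and
includes the intervening non-defensive genes, so content fractions can
express the non-defensive complement.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    DefenseAnnotation,
    DefenseSystem,
    GeneRecord,
    GeneStatus,
    Island,
    MAGRecord,
)

#: hits of this family count as defense units but not toward the
#: distinct-family minimum
UNKNOWN_FAMILY = "unknown"


def _units_gene_mode(
    genes_by_contig: Dict[str, List[GeneRecord]],
    hits: Sequence[DefenseAnnotation],
    gene_index: Dict[str, GeneRecord],
) -> Dict[str, List[Tuple[int, Tuple[str, ...], str]]]:
    """Per contig: (position, member gene ids, family) per unit, sorted."""
    units: Dict[str, list] = defaultdict(list)
    for hit in hits:
        gene = gene_index.get(hit.gene_id)
        if gene is None:
            raise ValueError(f"defense hit for unknown gene {hit.gene_id!r}")
        units[gene.contig_id].append((gene.ordinal, (gene.gene_id,), hit.family))
    for contig in units:
        units[contig].sort()
    return units


def _units_system_mode(
    systems: Sequence[DefenseSystem],
    gene_index: Dict[str, GeneRecord],
) -> Dict[str, List[Tuple[int, Tuple[str, ...], str]]]:
    units: Dict[str, list] = defaultdict(list)
    for sys in systems:
        ordinals = [gene_index[g].ordinal for g in sys.member_gene_ids]
        units[sys.contig_id].append(
            (min(ordinals), tuple(sys.member_gene_ids), sys.family)
        )
    for contig in units:
        units[contig].sort()
    return units


def call_islands(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    *,
    systems: Optional[Sequence[DefenseSystem]] = None,
    unit: str = "gene",
    gap_max: int = 10,
    min_units: int = 5,
    min_families: int = 3,
) -> List[Island]:
    """Call maximal defense islands per contig.

    Units are chained left-to-right while the number of genes strictly
    between consecutive unit positions is <= gap_max; maximal chains
    meeting the unit and family minima are emitted.  Islands never span
    contigs.
    """
    if unit not in ("gene", "system"):
        raise ValueError("unit must be 'gene' or 'system'")
    gene_index = {g.gene_id: g for g in genes}
    genes_by_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    for g in genes:
        genes_by_contig[g.contig_id].append(g)

    if unit == "gene":
        units = _units_gene_mode(genes_by_contig, hits, gene_index)
    else:
        if systems is None:
            raise ValueError("unit='system' requires assembled systems")
        units = _units_system_mode(systems, gene_index)

    mag_of = {g.contig_id: g.mag_id for g in genes}
    islands: List[Island] = []
    counter = 0
    for contig in sorted(units):
        chain: List[Tuple[int, Tuple[str, ...], str]] = []
        chains: List[list] = []
        for item in units[contig]:
            if chain and item[0] - chain[-1][0] - 1 > gap_max:
                chains.append(chain)
                chain = []
            chain.append(item)
        if chain:
            chains.append(chain)
        for ch in chains:
            families = {fam for _, _, fam in ch if fam != UNKNOWN_FAMILY}
            if len(ch) < min_units or len(families) < min_families:
                continue
            member_ids = tuple(gid for _, gids, _ in ch for gid in gids)
            ordinals = [gene_index[gid].ordinal for gid in member_ids]
            counter += 1
            islands.append(
                Island(
                    island_id=f"DI{counter:05d}",
                    mag_id=mag_of[contig],
                    contig_id=contig,
                    first_ordinal=min(ordinals),
                    last_ordinal=max(ordinals),
                    member_gene_ids=member_ids,
                    families=frozenset(families),
                    counting_unit=unit,
                )
            )
    return islands


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def gene_in_island(gene: GeneRecord, islands_by_contig: Dict[str, List[Island]]) -> bool:
    return any(
        isl.contains_ordinal(gene.ordinal)
        for isl in islands_by_contig.get(gene.contig_id, ())
    )


def index_islands(islands: Iterable[Island]) -> Dict[str, List[Island]]:
    by_contig: Dict[str, List[Island]] = defaultdict(list)
    for isl in islands:
        by_contig[isl.contig_id].append(isl)
    return by_contig


def island_summary(
    islands: Sequence[Island],
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    mags: Optional[Sequence[MAGRecord]] = None,
) -> dict:
    """Length distribution, per-MAG density and defensive content fraction.

    ``length_genes`` counts every gene in the island span; the content
    fraction is defense genes in islands over all genes in islands (its
    complement is the non-defensive slice).
    """
    defense_ids = {h.gene_id for h in hits}
    by_contig = index_islands(islands)
    lengths = [isl.length_genes for isl in islands]

    genes_in_islands = 0
    defense_in_islands = 0
    for g in genes:
        if gene_in_island(g, by_contig):
            genes_in_islands += 1
            if g.gene_id in defense_ids:
                defense_in_islands += 1

    densities: Dict[str, float] = {}
    if mags is not None:
        n_per_mag: Dict[str, int] = defaultdict(int)
        for isl in islands:
            n_per_mag[isl.mag_id] += 1
        for mag in mags:
            densities[mag.mag_id] = n_per_mag.get(mag.mag_id, 0) / (mag.size_bp / 1000.0)

    frac = defense_in_islands / genes_in_islands if genes_in_islands else float("nan")
    return {
        "n_islands": len(islands),
        "lengths_genes": lengths,
        "median_length_genes": float(np.median(lengths)) if lengths else float("nan"),
        "density_per_mag_per_kb": densities,
        "genes_in_islands": genes_in_islands,
        "defense_genes_in_islands": defense_in_islands,
        "defense_content_fraction": frac,
        "non_defense_content_fraction": 1.0 - frac if genes_in_islands else float("nan"),
    }


def skew_ratio(
    statuses: Iterable[GeneStatus], include_solitary: bool = True
) -> Optional[float]:
    """(#genes in complete systems - #genes in incomplete systems) /
    (their sum) over the supplied defense genes.

    Solitary genes count in the incomplete class by default (the binary
    complete/incomplete split leaves them open; flag to exclude).  Returns
    None when the denominator is 0.
    """
    c = i = 0
    for st in statuses:
        if st is GeneStatus.COMPLETE:
            c += 1
        elif st is GeneStatus.INCOMPLETE:
            i += 1
        elif include_solitary:
            i += 1
    if c + i == 0:
        return None
    return (c - i) / (c + i)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with Haldane-Anscombe +0.5 on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def family_island_enrichment(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    islands: Sequence[Island],
) -> List[dict]:
    """Per-family 2x2 Fisher test of in-island vs outside representation.

    Table per family f: [genes of f vs genes of other families] x
    [inside islands vs outside].  Returns rows with observed counts, odds
    ratio (+0.5 on zero cells), two-sided Fisher p and BH-adjusted q.
    """
    by_contig = index_islands(islands)
    gene_index = {g.gene_id: g for g in genes}
    fam_in: Dict[str, int] = defaultdict(int)
    fam_out: Dict[str, int] = defaultdict(int)
    for hit in hits:
        g = gene_index[hit.gene_id]
        if gene_in_island(g, by_contig):
            fam_in[hit.family] += 1
        else:
            fam_out[hit.family] += 1
    total_in = sum(fam_in.values())
    total_out = sum(fam_out.values())

    rows = []
    families = sorted(set(fam_in) | set(fam_out))
    for fam in families:
        a = fam_in.get(fam, 0)
        c = fam_out.get(fam, 0)
        b = total_in - a
        d = total_out - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "family": fam,
                "in_island": a,
                "in_island_other": b,
                "outside": c,
                "outside_other": d,
                "odds_ratio": odds_ratio_2x2(a, b, c, d),
                "p": float(p),
            }
        )
    if rows:
        qs = multipletests([r["p"] for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, qs):
            r["q"] = float(q)
    return rows
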