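"""Independent reference implementations used only to check the package.

These deliberately take the slow, direct route (window enumeration,
exhaustive mutation listing, explicit matrix construction) and share no
code with the library paths they validate.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id


def brute_force_islands(
    unit_positions: Sequence[int],
    unit_families: Sequence[str],
    gap_max: int,
    min_units: int,
    min_families: int,
    family_not_counted: str = "unknown",
) -> List[Tuple[int, int, Tuple[int, ...]]]:
    """Enumerate maximal valid defense arrays by O(n^2) window scanning.

    Returns (first_position, last_position, member_positions) per island,
    sorted.  A window [i, j] of the position-sorted unit list is valid when
    every consecutive gap inside it is <= gap_max; it is maximal when it
    cannot be extended left or right without breaking the gap rule.
    """
    order = np.argsort(unit_positions, kind="stable")
    pos = [unit_positions[k] for k in order]
    fams = [unit_families[k] for k in order]
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i, n):
            gaps_ok = all(pos[k + 1] - pos[k] - 1 <= gap_max for k in range(i, j))
            if not gaps_ok:
                continue
            left_ext = i > 0 and pos[i] - pos[i - 1] - 1 <= gap_max
            right_ext = j < n - 1 and pos[j + 1] - pos[j] - 1 <= gap_max
            if left_ext or right_ext:
                continue
            members = tuple(pos[i : j + 1])
            distinct = {f for f in fams[i : j + 1] if f != family_not_counted}
            if len(members) >= min_units and len(distinct) >= min_families:
                out.append((pos[i], pos[j], members))
    return sorted(out)


def enumerate_codon_sites(codon: str) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site counts by listing all nine mutations."""
    table = unambiguous_dna_by_id[1]
    aa = table.forward_table[codon]
    stops = set(table.stop_codons)
    s_total = 0.0
    for pos in range(3):
        outcomes = []
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1 :]
            if mut in stops:
                continue
            outcomes.append(table.forward_table[mut] == aa)
        if outcomes:
            s_total += sum(outcomes) / len(outcomes)
    return s_total, 3.0 - s_total


def n50_by_cut_scan(lengths: Sequence[int]) -> int:
    """N50 by scanning every cut point of the descending-sorted list."""
    desc = sorted(lengths, reverse=True)
    half = sum(desc) / 2.0
    for k in range(1, len(desc) + 1):
        if sum(desc[:k]) >= half:
            return desc[k - 1]
    raise AssertionError


def vcv_diagonal_mean(tree) -> float:
    """Mean of the phylogenetic variance-covariance diagonal.

    The full VCV matrix is built from the definition VCV[i, j] = depth of
    MRCA(taxon_i, taxon_j), using dendropy's own MRCA search and
    root-distance traversal; the diagonal mean is returned."""
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    n = len(taxa)
    vcv = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mrca = tree.mrca(taxa=[taxa[i], taxa[j]])
            vcv[i, j] = vcv[j, i] = mrca.distance_from_root()
    return float(np.mean(np.diag(vcv)))


def spearman_no_ties(x: Sequence[float], y: Sequence[float]) -> float:
    """Classical rank-difference formula (valid without ties)."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
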