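"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

For each codon, every one of the nine single-nucleotide changes is
classified as synonymous or nonsynonymous under the standard genetic
code; changes creating stop codons are excluded from the per-position
denominator.  Synonymous sites per codon are the sum over positions of
the synonymous fraction; nonsynonymous sites are the complement to 3.

Differences between two aligned codons are averaged with equal weight
over all minimal mutational pathways, excluding pathways that pass
through a stop codon.  Proportions are corrected for multiple hits with
the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).  Pairs with dS > 1 are
flagged as saturated and discarded from omega summaries.
"""

from __future__ import annotations

import math
from collections import defaultdict
from functools import lru_cache
from itertools import permutations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .types import SelectionEstimate

_NUCS = "ACGT"
_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)


def _translate(codon: str) -> Optional[str]:
    """Amino acid of a sense codon, None for stops."""
    return _AA.get(codon)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position the synonymous fraction is #synonymous / #non-stop over
    the three single-nucleotide changes; s + n = 3 always.
    """
    codon = codon.upper()
    if codon not in _AA:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mutated = codon[:pos] + nuc + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                continue
            non_stop += 1
            if _AA[mutated] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> Optional[Tuple[float, float]]:
    """(Sd, Nd) between two sense codons, averaged over minimal mutational
    pathways that avoid stop codons.  None if every pathway is blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_counts: List[int] = []
    non_counts: List[int] = []
    for order in permutations(diff):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _AA[cur] == _AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            syn_counts.append(syn)
            non_counts.append(non)
    if not syn_counts:
        return None
    return (
        sum(syn_counts) / len(syn_counts),
        sum(non_counts) / len(non_counts),
    )


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in _NUCS for b in codon) and codon in _AA


def ng86_pair(seq1: str, seq2: str, pair_id: str = "") -> SelectionEstimate:
    """NG86 estimates for one codon-aligned sequence pair.

    Codon positions with gaps, ambiguous bases or stop codons in either
    sequence are skipped pairwise; codon pairs whose every mutational
    pathway is stop-blocked are skipped entirely (sites and differences).
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    if len(s1) % 3:
        raise ValueError("alignment length must be a multiple of 3")

    S = N = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if not (_valid_codon(c1) and _valid_codon(c2)):
            continue
        diffs = _pathway_differences(c1, c2)
        if diffs is None:
            continue
        sa, na = ng86_sites(c1)
        sb, nb = ng86_sites(c2)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        n_codons += 1

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)

    discarded = False
    reason = ""
    omega: Optional[float] = None
    if n_codons == 0:
        discarded, reason = True, "no_comparable_codons"
    elif ds is None or dn is None:
        discarded, reason = True, "jukes_cantor_undefined"
    elif ds > 1.0:
        discarded, reason = True, "saturated"
        omega = dn / ds if ds > 0 else None
    elif ds == 0.0:
        reason = "ds_zero"
    else:
        omega = dn / ds
    return SelectionEstimate(
        pair_id=pair_id,
        s_sites=S,
        n_sites=N,
        sd=Sd,
        nd=Nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        omega=omega,
        discarded=discarded,
        reason=reason,
    )


def cluster_omega(
    clusters: Mapping[str, Sequence[str]],
    sequences: Mapping[str, str],
    family_of: Optional[Mapping[str, str]] = None,
) -> dict:
    """Estimate omega over all within-cluster pairs and summarize per
    family.

    ``clusters`` maps cluster id -> member sequence ids (codon-aligned
    within each cluster); singletons are dropped.  ``family_of`` maps
    cluster id -> defense family (one summary bucket per family;
    defaults to the cluster id itself).  Saturated pairs (dS > 1) are
    discarded from the omega distributions and reported as a fraction.
    """
    estimates: List[SelectionEstimate] = []
    per_family: Dict[str, List[float]] = defaultdict(list)
    n_discarded = 0
    for cluster_id in sorted(clusters):
        members = list(clusters[cluster_id])
        if len(members) < 2:
            continue
        fam = (family_of or {}).get(cluster_id, cluster_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                est = ng86_pair(sequences[a], sequences[b], pair_id=f"{a}|{b}")
                estimates.append(est)
                if est.discarded:
                    n_discarded += 1
                elif est.omega is not None:
                    per_family[fam].append(est.omega)

    summaries = {}
    for fam, omegas in sorted(per_family.items()):
        arr = np.asarray(omegas)
        summaries[fam] = {
            "n_pairs": int(arr.size),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    n_total = len(estimates)
    return {
        "estimates": estimates,
        "per_family": summaries,
        "n_pairs": n_total,
        "discarded_fraction": n_discarded / n_total if n_total else float("nan"),
    }


def read_clusters(path) -> Dict[str, List[str]]:
    """Read a cluster TSV: cluster_id <tab> seq_id (one member per row)."""
    clusters: Dict[str, List[str]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cluster_id, seq_id = line.split("\t")[:2]
            clusters[cluster_id].append(seq_id)
    return dict(clusters)
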