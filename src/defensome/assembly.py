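"""Defense-system assembly from per-gene defense hits.

A system family is described by a rule: the set of mandatory and accessory
gene names, a minimum number of mandatory genes (MG), a minimum total gene
count (SG), and a maximum gap between consecutive member genes (d_max,
counted as genes strictly between them).  Hits of one family on one contig
are chained greedily left-to-right while the gap stays within d_max; each
chain is a system, complete iff it reaches both MG and SG.

When the input annotations already carry system assignments (system_id
set), assembly is skipped and the provided assignment is authoritative.
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .types import DefenseAnnotation, DefenseSystem, GeneRecord, GeneStatus


@dataclass(frozen=True)
class FamilyRule:
    """Assembly rule for one defense family."""

    family: str
    mandatory_genes: frozenset
    accessory_genes: frozenset
    min_mandatory: int  # MG
    min_total: int      # SG
    max_gap: int        # d_max, intervening genes

    def __post_init__(self) -> None:
        if self.max_gap < 0 or self.min_mandatory < 0 or self.min_total < 1:
            raise ValueError(f"rule for {self.family}: invalid thresholds")


#: families without an explicit rule behave as single-gene systems: every
#: lone hit is a complete singleton system.
def single_gene_rule(family: str) -> FamilyRule:
    return FamilyRule(
        family=family,
        mandatory_genes=frozenset(),
        accessory_genes=frozenset(),
        min_mandatory=0,
        min_total=1,
        max_gap=0,
    )


class RuleSet:
    """Mapping family -> FamilyRule with a single-gene fallback."""

    def __init__(self, rules: Optional[Dict[str, FamilyRule]] = None):
        self._rules: Dict[str, FamilyRule] = dict(rules or {})

    def __contains__(self, family: str) -> bool:
        return family in self._rules

    def __getitem__(self, family: str) -> FamilyRule:
        return self._rules[family]

    def get(self, family: str) -> FamilyRule:
        return self._rules.get(family) or single_gene_rule(family)

    def add(self, rule: FamilyRule) -> None:
        self._rules[rule.family] = rule

    @property
    def families(self) -> List[str]:
        return sorted(self._rules)


def read_rules(path) -> RuleSet:
    """Read a rules TSV with columns family, gene_name, role, MG, SG, d_max
    (one row per gene name; thresholds repeated per family)."""
    per_family: Dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                idx = {c: header.index(c) for c in header}
                continue
            fam = row[idx["family"]]
            entry = per_family.setdefault(
                fam,
                {"mandatory": set(), "accessory": set(), "MG": 0, "SG": 1, "d_max": 0},
            )
            role = row[idx["role"]].strip().lower()
            if role == "mandatory":
                entry["mandatory"].add(row[idx["gene_name"]])
            else:
                entry["accessory"].add(row[idx["gene_name"]])
            entry["MG"] = int(row[idx["MG"]])
            entry["SG"] = int(row[idx["SG"]])
            entry["d_max"] = int(row[idx["d_max"]])
    rules = RuleSet()
    for fam, entry in per_family.items():
        rules.add(
            FamilyRule(
                family=fam,
                mandatory_genes=frozenset(entry["mandatory"]),
                accessory_genes=frozenset(entry["accessory"]),
                min_mandatory=entry["MG"],
                min_total=entry["SG"],
                max_gap=entry["d_max"],
            )
        )
    return rules


def write_rules(rules: RuleSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# assembly rules: MG=min mandatory, SG=min total, d_max=max gap (genes)\n")
        fh.write("family\tgene_name\trole\tMG\tSG\td_max\n")
        for fam in rules.families:
            r = rules[fam]
            for name in sorted(r.mandatory_genes):
                fh.write(f"{fam}\t{name}\tmandatory\t{r.min_mandatory}\t{r.min_total}\t{r.max_gap}\n")
            for name in sorted(r.accessory_genes):
                fh.write(f"{fam}\t{name}\taccessory\t{r.min_mandatory}\t{r.min_total}\t{r.max_gap}\n")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _join_hits(
    genes: Sequence[GeneRecord], hits: Sequence[DefenseAnnotation]
) -> List[Tuple[GeneRecord, DefenseAnnotation]]:
    by_id = {g.gene_id: g for g in genes}
    joined = []
    for hit in hits:
        gene = by_id.get(hit.gene_id)
        if gene is None:
            raise ValueError(f"defense hit for unknown gene {hit.gene_id!r}")
        joined.append((gene, hit))
    return joined


def _chain_complete(
    members: List[Tuple[GeneRecord, DefenseAnnotation]], rule: FamilyRule
) -> bool:
    if rule.mandatory_genes:
        n_mand = sum(1 for _, h in members if h.gene_name in rule.mandatory_genes)
    else:
        n_mand = len(members)  # single-gene fallback: every hit counts
    return n_mand >= rule.min_mandatory and len(members) >= rule.min_total


def assemble_systems(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    rules: Optional[RuleSet] = None,
) -> Tuple[List[DefenseSystem], Dict[str, GeneStatus]]:
    """Assemble defense systems and classify every defense gene.

    Returns (systems, status) where status maps gene_id to
    complete-member / incomplete-member / solitary.  A chain of a single
    gene that does not form a complete system leaves its gene solitary.

    If any hit already carries a system_id the provided assignment is used
    verbatim: assigned genes are complete-system members when their group
    satisfies the family rule (or when no rule is available), and
    unassigned genes are solitary.
    """
    rules = rules or RuleSet()
    joined = _join_hits(genes, hits)

    if any(h.system_id for _, h in joined):
        return _systems_from_assignments(joined, rules)

    # sanity: warn once per unknown gene_name under an explicit rule
    for _, hit in joined:
        if hit.family in rules:
            r = rules[hit.family]
            if r.mandatory_genes and hit.gene_name not in (
                r.mandatory_genes | r.accessory_genes
            ):
                warnings.warn(
                    f"gene_name {hit.gene_name!r} not in rule for family "
                    f"{hit.family!r}; counted as accessory",
                    stacklevel=2,
                )

    by_group: Dict[Tuple[str, str], list] = defaultdict(list)
    for gene, hit in joined:
        by_group[(gene.contig_id, hit.family)].append((gene, hit))

    systems: List[DefenseSystem] = []
    status: Dict[str, GeneStatus] = {}
    counter = 0
    for (contig, family) in sorted(by_group):
        members = sorted(by_group[(contig, family)], key=lambda gh: gh[0].ordinal)
        rule = rules.get(family)
        chain: List[Tuple[GeneRecord, DefenseAnnotation]] = []
        chains: List[list] = []
        for gene, hit in members:
            if chain and gene.ordinal - chain[-1][0].ordinal - 1 > rule.max_gap:
                chains.append(chain)
                chain = []
            chain.append((gene, hit))
        if chain:
            chains.append(chain)
        for ch in chains:
            complete = _chain_complete(ch, rule)
            counter += 1
            sys_id = f"{contig}:{family}:{counter}"
            if len(ch) == 1 and not complete:
                status[ch[0][0].gene_id] = GeneStatus.SOLITARY
                continue
            systems.append(
                DefenseSystem(
                    system_id=sys_id,
                    family=family,
                    member_gene_ids=tuple(g.gene_id for g, _ in ch),
                    contig_id=contig,
                    complete=complete,
                )
            )
            st = GeneStatus.COMPLETE if complete else GeneStatus.INCOMPLETE
            for g, _ in ch:
                status[g.gene_id] = st
    return systems, status


def _systems_from_assignments(
    joined: List[Tuple[GeneRecord, DefenseAnnotation]], rules: RuleSet
) -> Tuple[List[DefenseSystem], Dict[str, GeneStatus]]:
    by_system: Dict[str, list] = defaultdict(list)
    status: Dict[str, GeneStatus] = {}
    for gene, hit in joined:
        if hit.system_id:
            by_system[hit.system_id].append((gene, hit))
        else:
            status[gene.gene_id] = GeneStatus.SOLITARY
    systems = []
    for sys_id in sorted(by_system):
        members = sorted(by_system[sys_id], key=lambda gh: gh[0].ordinal)
        family = members[0][1].family
        if family in rules:
            complete = _chain_complete(members, rules[family])
        else:
            complete = True  # upstream tool's assignment trusted
        systems.append(
            DefenseSystem(
                system_id=sys_id,
                family=family,
                member_gene_ids=tuple(g.gene_id for g, _ in members),
                contig_id=members[0][0].contig_id,
                complete=complete,
            )
        )
        st = GeneStatus.COMPLETE if complete else GeneStatus.INCOMPLETE
        for g, _ in members:
            status[g.gene_id] = st
    return systems, status


def defense_gene_inventory(
    systems: Sequence[DefenseSystem],
    status: Dict[str, GeneStatus],
    hits: Sequence[DefenseAnnotation],
) -> Dict[str, Dict[str, int]]:
    """Per-family counts of systems, complete systems, defense genes and
    solitary genes, plus an ``_total`` row.  Genes in complete systems +
    genes in incomplete systems + solitary genes = total defense genes."""
    fam_of = {h.gene_id: h.family for h in hits}
    out: Dict[str, Dict[str, int]] = defaultdict(
        lambda: {
            "n_systems": 0,
            "n_complete_systems": 0,
            "n_defense_genes": 0,
            "n_solitary": 0,
            "n_genes_complete": 0,
            "n_genes_incomplete": 0,
        }
    )
    for sys in systems:
        row = out[sys.family]
        row["n_systems"] += 1
        if sys.complete:
            row["n_complete_systems"] += 1
    for gene_id, st in status.items():
        row = out[fam_of[gene_id]]
        row["n_defense_genes"] += 1
        if st is GeneStatus.SOLITARY:
            row["n_solitary"] += 1
        elif st is GeneStatus.COMPLETE:
            row["n_genes_complete"] += 1
        else:
            row["n_genes_incomplete"] += 1
    total = {
        k: sum(row[k] for row in out.values())
        for k in (
            "n_systems",
            "n_complete_systems",
            "n_defense_genes",
            "n_solitary",
            "n_genes_complete",
            "n_genes_incomplete",
        )
    }
    result = dict(out)
    result["_total"] = total
    return result
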