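"""Core domain types shared by every analysis stage.

Coordinate convention: all genomic coordinates are 1-based and inclusive
(GFF style).  BED input is converted at the I/O boundary.  Gene order on a
contig is captured by a 0-based ``ordinal`` assigned by ascending start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

MGE_CLASSES = ("plasmid", "prophage", "ICE_IME", "integron")

RRNA_CLASSES = frozenset({"5S", "16S", "23S"})


class GeneStatus(str, Enum):
    """Status of a defense gene after system assembly.

    Every defense gene carries exactly one status: member of a complete
    system, member of an incomplete (partial) system, or solitary.
    """

    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    SOLITARY = "solitary"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a contig.

    ``ordinal`` is the 0-based rank of the gene among all genes on its
    contig sorted by ascending start (ties: ascending end, then gene_id).
    All gap rules in the package count genes *strictly between* two genes,
    i.e. ``ord_b - ord_a - 1`` for ordinals ``a < b``.
    """

    mag_id: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DefenseAnnotation:
    """A defense-gene hit (DefenseFinder-style) attached to one gene.

    ``role`` distinguishes the mandatory components of a system's genetic
    organization from accessory ones; ``system_id`` is set when the
    upstream tool already assembled the hit into a system.
    """

    gene_id: str
    family: str
    gene_name: str
    role: str
    system_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"defense annotation for {self.gene_id}: empty family")
        if self.role not in ("mandatory", "accessory"):
            raise ValueError(
                f"defense annotation for {self.gene_id}: role must be "
                f"'mandatory' or 'accessory', got {self.role!r}"
            )


@dataclass(frozen=True)
class MGEInterval:
    """A mobile-genetic-element span on a contig (1-based inclusive)."""

    contig_id: str
    start: int
    end: int
    mge_class: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"MGE interval on {self.contig_id}: end ({self.end}) < start ({self.start})"
            )
        if self.mge_class not in MGE_CLASSES:
            raise ValueError(
                f"unknown MGE class {self.mge_class!r}; allowed: {', '.join(MGE_CLASSES)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "MGEInterval") -> bool:
        return self.contig_id == other.contig_id and not (
            self.end < other.start or other.end < self.start
        )


@dataclass(frozen=True)
class MAGRecord:
    """Metadata of one metagenome-assembled genome."""

    mag_id: str
    habitat: str
    size_bp: int
    completeness: float
    contamination: float
    trna_count: int
    rrna_classes: frozenset
    contig_lengths: tuple
    sub_habitat: str = ""
    n50: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.mag_id}: completeness out of [0, 100]")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"{self.mag_id}: contamination out of [0, 100]")
        if self.contig_lengths and self.size_bp != sum(self.contig_lengths):
            raise ValueError(
                f"{self.mag_id}: size_bp ({self.size_bp}) != sum of contig lengths "
                f"({sum(self.contig_lengths)})"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A short variant (SNP or indel) mapped onto an analyzed gene region.

    ``position`` is the 1-based contig coordinate of the variant.  ``region``
    and ``var_type`` are filled in by classification; unclassified SNPs keep
    ``SNP_unclassified``.
    """

    gene_id: str
    position: int
    var_type: str
    region: str
    allele_frequency: float
    supporting_reads: int

    VAR_TYPES = ("SNP_synonymous", "SNP_nonsynonymous", "SNP_unclassified", "indel")
    REGIONS = ("gene_body", "upstream", "unassigned")

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"variant {self.gene_id}@{self.position}: allele_frequency out of [0, 1]"
            )
        if self.supporting_reads < 0:
            raise ValueError(
                f"variant {self.gene_id}@{self.position}: negative supporting_reads"
            )
        if self.var_type not in self.VAR_TYPES:
            raise ValueError(f"unknown var_type {self.var_type!r}")
        if self.region not in self.REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class DefenseSystem:
    """An assembled defense system: colocalized genes of one family."""

    system_id: str
    family: str
    member_gene_ids: tuple
    contig_id: str
    complete: bool

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


@dataclass(frozen=True)
class Island:
    """A maximal array of clustered defense units on one contig.

    ``length_genes`` counts *all* genes in the span, defensive or not,
    because island content statistics need the non-defensive complement.
    """

    island_id: str
    mag_id: str
    contig_id: str
    first_ordinal: int
    last_ordinal: int
    member_gene_ids: tuple
    families: frozenset
    counting_unit: str = "gene"

    @property
    def length_genes(self) -> int:
        return self.last_ordinal - self.first_ordinal + 1

    @property
    def n_units(self) -> int:
        return len(self.member_gene_ids)

    def contains_ordinal(self, ordinal: int) -> bool:
        return self.first_ordinal <= ordinal <= self.last_ordinal


@dataclass(frozen=True)
class EnrichmentCell:
    """Observed vs independence-expected count for a family x category cell."""

    family: str
    category: str
    observed: int
    expected: float
    oe: float
    chi2_contribution: float


@dataclass(frozen=True)
class PairAssociation:
    """2x2 association of one unordered family pair, inside vs outside islands."""

    family_a: str
    family_b: str
    pairs_in: int
    pairs_out: int
    other_pairs_in: int
    other_pairs_out: int
    odds_ratio: float
    fisher_p: float


@dataclass(frozen=True)
class SelectionEstimate:
    """Pairwise NG86 estimates for one codon-aligned sequence pair.

    ``discarded`` is set for saturated pairs (dS > 1) and for degenerate
    cases where the Jukes-Cantor correction is undefined; ``reason`` says
    which.  ``omega`` is None whenever dS is 0 or undefined.
    """

    pair_id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: Optional[float]
    dn: Optional[float]
    omega: Optional[float]
    discarded: bool
    reason: str = ""


@dataclass
class GeneVariantSummary:
    """Per-gene summary of retained high-frequency variants."""

    gene_id: str
    family: str
    analyzed_length_bp: int
    n_snp: int = 0
    n_indel: int = 0
    has_high_frequency_variant: bool = False
    type_fractions: dict = field(default_factory=dict)
    region_fractions: dict = field(default_factory=dict)

    @property
    def density_per_kb(self) -> float:
        return (self.n_snp + self.n_indel) / (self.analyzed_length_bp / 1000.0)
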