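"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume:
per-contig gene order, defense genes scattered at a background rate and
concentrated in planted defense islands, MGE intervals with per-class
defense-carriage biases, high-frequency variant enrichment in selected
families, and codon-aligned sequence pairs evolved at a known omega.

A single integer seed drives a hierarchical stream (one spawned
substream per MAG) so that growing the cohort does not reshuffle
earlier MAGs, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io as dio
from .colocalization import tag_mge_membership
from .qc import compute_n50
from .types import (
    MGE_CLASSES,
    DefenseAnnotation,
    GeneRecord,
    MAGRecord,
    MGEInterval,
    VariantRecord,
)

#: default defense-family catalog (20 families, weights loosely
#: log-uniform so a few families dominate, as in real defensomes)
DEFAULT_FAMILIES: Tuple[str, ...] = (
    "RM", "CRISPR-Cas", "CBASS", "AbiEii", "BREX", "Gabija", "Hachiman",
    "Thoeris", "Zorya", "PsyrTA", "ShosTA", "Lamassu", "RosmerTA",
    "Rst_PARIS", "SoFIC", "Menshen", "Shango", "Dodola", "Septu", "Wadjet",
)


def _default_weights() -> Tuple[float, ...]:
    w = np.logspace(0, -1.3, num=len(DEFAULT_FAMILIES))
    return tuple(w / w.sum())


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults define the desk-scale
    study conditions used throughout the tests."""

    seed: int = 0
    n_mags: int = 30
    habitats: Tuple[str, ...] = ("soil", "marine", "human_gut")
    contigs_per_mag: int = 2
    genes_per_contig: int = 250
    mean_gene_length: int = 900
    gene_length_sd: int = 200
    min_gene_length: int = 300
    intergenic_mean: int = 120

    families: Tuple[str, ...] = DEFAULT_FAMILIES
    family_weights: Tuple[float, ...] = field(default_factory=_default_weights)
    defense_rate: float = 0.03

    islands_per_mag: int = 2
    island_units_range: Tuple[int, int] = (5, 8)
    island_gap_range: Tuple[int, int] = (0, 3)
    island_min_families: int = 3
    gap_max: int = 10
    strict_spacing: bool = True

    mge_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "plasmid": 0.8, "prophage": 0.8, "ICE_IME": 0.5, "integron": 0.2
        }
    )
    mge_length_range: Tuple[int, int] = (10_000, 40_000)
    carriage_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {
            "plasmid": 3.0, "prophage": 2.5, "ICE_IME": 4.0, "integron": 2.0
        }
    )

    qc_fail_fraction: float = 0.1

    # variant model
    variant_rate: float = 1.5          # mean variants per defense gene
    high_freq_rate: float = 0.25       # P(a variant passes the 25%/10-read gate)
    indel_fraction: float = 0.2
    enriched_families: Mapping[str, float] = field(default_factory=dict)

    # codon-pair model
    omega: float = 0.2
    divergence: float = 0.3            # proposed changes per nucleotide site
    n_codons: int = 300
    n_pairs: int = 200

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for rate in (self.defense_rate, self.variant_rate, self.high_freq_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, keyed the way the emitted files are."""

    planted_islands: List[dict] = field(default_factory=list)
    mge_membership: Dict[str, str] = field(default_factory=dict)
    high_frequency_genes: Dict[str, bool] = field(default_factory=dict)
    pair_association: Optional[dict] = None
    omega_true: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    mags: List[MAGRecord]
    genes: Dict[str, List[GeneRecord]]          # mag_id -> genes
    hits: Dict[str, List[DefenseAnnotation]]    # mag_id -> defense hits
    mges: Dict[str, List[MGEInterval]]          # mag_id -> intervals
    truth: GroundTruth

    def all_genes(self) -> List[GeneRecord]:
        return [g for mag_id in sorted(self.genes) for g in self.genes[mag_id]]

    def all_hits(self) -> List[DefenseAnnotation]:
        return [h for mag_id in sorted(self.hits) for h in self.hits[mag_id]]

    def all_mges(self) -> List[MGEInterval]:
        return [m for mag_id in sorted(self.mges) for m in self.mges[mag_id]]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_gene_table(self.all_genes(), out / "genes.tsv")
        dio.write_defense_annotations(self.all_hits(), out / "defense_hits.tsv")
        dio.write_mge_bed(self.all_mges(), out / "mges.bed")
        dio.write_mag_metadata(self.mags, out / "mags.tsv")
        (out / "truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

def _make_contig_genes(
    rng: np.random.Generator,
    mag_id: str,
    contig_id: str,
    n_genes: int,
    cfg: SimulationConfig,
) -> Tuple[List[GeneRecord], int]:
    """Lay out non-overlapping genes left to right; returns (genes, contig_bp)."""
    genes: List[GeneRecord] = []
    pos = 1
    for i in range(n_genes):
        gap = int(rng.exponential(cfg.intergenic_mean))
        length = int(
            np.clip(
                rng.normal(cfg.mean_gene_length, cfg.gene_length_sd),
                cfg.min_gene_length,
                None,
            )
        )
        start = pos + gap
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                mag_id=mag_id,
                contig_id=contig_id,
                gene_id=f"{contig_id}_g{i:04d}",
                start=start,
                end=end,
                strand=strand,
                ordinal=i,
            )
        )
        pos = end + 1
    contig_bp = pos + int(rng.integers(200, 1000))
    return genes, contig_bp


def _draw_island_families(
    rng: np.random.Generator, cfg: SimulationConfig, n_units: int
) -> List[str]:
    fams = list(
        rng.choice(cfg.families, size=n_units, p=list(cfg.family_weights))
    )
    # force the family minimum by replacing *duplicate* slots only, so no
    # existing family is accidentally erased
    distinct = list(dict.fromkeys(fams))
    need = cfg.island_min_families - len(distinct)
    if need > 0:
        seen: set = set()
        dup_slots = []
        for k, fam in enumerate(fams):
            if fam in seen:
                dup_slots.append(k)
            seen.add(fam)
        pool = [f for f in cfg.families if f not in distinct]
        extra = rng.choice(pool, size=need, replace=False)
        for slot, fam in zip(dup_slots, extra):
            fams[slot] = str(fam)
    return [str(f) for f in fams]


def _plant_islands_on_contig(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n_genes: int,
    n_islands: int,
) -> List[Tuple[List[int], List[str]]]:
    """Choose member ordinals and families for islands on one contig,
    keeping islands > gap_max apart so each stays maximal."""
    placed: List[Tuple[List[int], List[str]]] = []
    occupied: List[Tuple[int, int]] = []
    margin = cfg.gap_max + 1
    for _ in range(n_islands):
        for _attempt in range(200):
            n_units = int(rng.integers(cfg.island_units_range[0], cfg.island_units_range[1] + 1))
            gaps = rng.integers(
                cfg.island_gap_range[0], cfg.island_gap_range[1] + 1, size=n_units - 1
            )
            span = n_units + int(gaps.sum())
            if span + 2 * margin >= n_genes:
                continue
            start = int(rng.integers(margin, n_genes - span - margin))
            ordinals = [start]
            for gp in gaps:
                ordinals.append(ordinals[-1] + 1 + int(gp))
            lo, hi = ordinals[0] - margin, ordinals[-1] + margin
            if any(not (hi < o_lo or lo > o_hi) for o_lo, o_hi in occupied):
                continue
            occupied.append((lo, hi))
            placed.append((ordinals, _draw_island_families(rng, cfg, n_units)))
            break
    return placed


def _place_mges(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    contig_lengths: Dict[str, int],
) -> List[MGEInterval]:
    intervals: List[MGEInterval] = []
    for cls in MGE_CLASSES:
        n = rng.poisson(cfg.mge_rate.get(cls, 0.0))
        for _ in range(n):
            for _attempt in range(50):
                contig = str(rng.choice(sorted(contig_lengths)))
                total = contig_lengths[contig]
                length = int(rng.integers(*cfg.mge_length_range))
                if length >= total:
                    continue
                start = int(rng.integers(1, total - length))
                iv = MGEInterval(contig, start, start + length - 1, cls)
                if any(iv.overlaps(other) for other in intervals):
                    continue  # keep the emitted track conflict-free
                intervals.append(iv)
                break
    return intervals


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate gene tables, defense hits, MGE tracks, MAG metadata and a
    ground-truth manifest for a whole cohort."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    substreams = root.spawn(cfg.n_mags)

    mags: List[MAGRecord] = []
    genes: Dict[str, List[GeneRecord]] = {}
    hits: Dict[str, List[DefenseAnnotation]] = {}
    mges: Dict[str, List[MGEInterval]] = {}
    truth = GroundTruth()

    margin = cfg.gap_max + 1
    for m in range(cfg.n_mags):
        rng = np.random.Generator(np.random.PCG64(substreams[m]))
        mag_id = f"MAG{m:04d}"
        habitat = cfg.habitats[m % len(cfg.habitats)]

        mag_genes: List[GeneRecord] = []
        contig_lengths: Dict[str, int] = {}
        for c in range(cfg.contigs_per_mag):
            contig_id = f"{mag_id}_c{c}"
            cg, cbp = _make_contig_genes(rng, mag_id, contig_id, cfg.genes_per_contig, cfg)
            mag_genes.extend(cg)
            contig_lengths[contig_id] = cbp

        mag_mges = _place_mges(rng, cfg, contig_lengths)
        membership = tag_mge_membership(mag_genes, mag_mges)

        # islands
        mag_hits: List[DefenseAnnotation] = []
        island_ordinals: Dict[str, set] = {c: set() for c in contig_lengths}
        genes_by_contig: Dict[str, List[GeneRecord]] = {}
        for g in mag_genes:
            genes_by_contig.setdefault(g.contig_id, []).append(g)

        n_islands_left = cfg.islands_per_mag
        contigs_sorted = sorted(contig_lengths)
        per_contig_islands = {
            c: n_islands_left // len(contigs_sorted)
            + (1 if i < n_islands_left % len(contigs_sorted) else 0)
            for i, c in enumerate(contigs_sorted)
        }
        for contig in contigs_sorted:
            planted = _plant_islands_on_contig(
                rng, cfg, len(genes_by_contig[contig]), per_contig_islands[contig]
            )
            for ordinals, fams in planted:
                member_ids = []
                for o, fam in zip(ordinals, fams):
                    gene = genes_by_contig[contig][o]
                    member_ids.append(gene.gene_id)
                    mag_hits.append(_make_hit(rng, gene.gene_id, fam))
                    island_ordinals[contig].add(o)
                truth.planted_islands.append(
                    {
                        "mag_id": mag_id,
                        "contig_id": contig,
                        "first_ordinal": ordinals[0],
                        "last_ordinal": ordinals[-1],
                        "member_gene_ids": member_ids,
                        "families": sorted(set(fams)),
                    }
                )

        # background defense genes with MGE carriage bias
        for contig in contigs_sorted:
            taken = sorted(island_ordinals[contig])
            kept_background: List[int] = []
            for g in genes_by_contig[contig]:
                if g.ordinal in island_ordinals[contig]:
                    continue
                ctx = membership[g.gene_id]
                mult = cfg.carriage_multiplier.get(ctx, 1.0) if ctx != "chromosome" else 1.0
                p = min(cfg.defense_rate * mult, 0.9)
                if rng.random() >= p:
                    continue
                if cfg.strict_spacing:
                    near_island = any(abs(g.ordinal - o) <= margin for o in taken)
                    near_bg = any(abs(g.ordinal - o) <= margin for o in kept_background)
                    if near_island or near_bg:
                        continue
                kept_background.append(g.ordinal)
                fam = str(rng.choice(cfg.families, p=list(cfg.family_weights)))
                mag_hits.append(_make_hit(rng, g.gene_id, fam))

        for gid, ctx in membership.items():
            truth.mge_membership[gid] = ctx

        size_bp = sum(contig_lengths.values())
        completeness = float(rng.uniform(90, 100))
        contamination = float(rng.uniform(0, 5))
        trna = int(rng.integers(18, 23))
        rrna = frozenset({"5S", "16S", "23S"})
        if rng.random() < cfg.qc_fail_fraction:
            # degrade one random criterion to exercise the QC gate
            which = int(rng.integers(0, 3))
            if which == 0:
                completeness = float(rng.uniform(70, 89.9))
            elif which == 1:
                contamination = float(rng.uniform(5.1, 15))
            else:
                trna = int(rng.integers(5, 17))
        lengths = tuple(contig_lengths[c] for c in contigs_sorted)
        mags.append(
            MAGRecord(
                mag_id=mag_id,
                habitat=habitat,
                size_bp=size_bp,
                completeness=completeness,
                contamination=contamination,
                trna_count=trna,
                rrna_classes=rrna,
                contig_lengths=lengths,
                n50=compute_n50(lengths),
            )
        )
        genes[mag_id] = mag_genes
        hits[mag_id] = sorted(mag_hits, key=lambda h: h.gene_id)
        mges[mag_id] = mag_mges

    return SimulatedCohort(cfg, mags, genes, hits, mges, truth)


def _make_hit(rng: np.random.Generator, gene_id: str, family: str) -> DefenseAnnotation:
    return DefenseAnnotation(
        gene_id=gene_id,
        family=family,
        gene_name=f"{family}_p{int(rng.integers(1, 4))}",
        role="mandatory" if rng.random() < 0.7 else "accessory",
    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variants(
    genes: Sequence[GeneRecord],
    hits: Sequence[DefenseAnnotation],
    cfg: SimulationConfig,
    seed: Optional[int] = None,
) -> Tuple[List[VariantRecord], Dict[str, bool]]:
    """Draw variants over the analyzed regions of defense genes.

    Each defense gene receives Poisson(variant_rate) variants.  Whether a
    variant is high-frequency (passes the 25% / 10-read gate) is decided
    first -- at ``high_freq_rate`` times the family's enrichment
    multiplier -- then frequency and read support are drawn on the
    corresponding side of the gate, so truth flags are exact by
    construction.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    gene_index = {g.gene_id: g for g in genes}
    variants: List[VariantRecord] = []
    flags: Dict[str, bool] = {}
    for hit in sorted(hits, key=lambda h: h.gene_id):
        gene = gene_index[hit.gene_id]
        p_high = min(
            cfg.high_freq_rate * cfg.enriched_families.get(hit.family, 1.0), 0.95
        )
        n_var = rng.poisson(cfg.variant_rate)
        has_high = False
        for _ in range(n_var):
            if gene.strand == "+":
                lo, hi = max(1, gene.start - 200), gene.end
            else:
                lo, hi = gene.start, gene.end + 200
            position = int(rng.integers(lo, hi + 1))
            is_indel = rng.random() < cfg.indel_fraction
            if rng.random() < p_high:
                freq = float(rng.uniform(0.25, 1.0))
                reads = int(rng.integers(10, 80))
                has_high = True
            else:
                if rng.random() < 0.5:
                    freq = float(rng.uniform(0.01, 0.2499))
                    reads = int(rng.integers(0, 80))
                else:
                    freq = float(rng.uniform(0.25, 1.0))
                    reads = int(rng.integers(0, 10))
            variants.append(
                VariantRecord(
                    gene_id=gene.gene_id,
                    position=position,
                    var_type="indel" if is_indel else "SNP_unclassified",
                    region="unassigned",
                    allele_frequency=freq,
                    supporting_reads=reads,
                )
            )
        flags[gene.gene_id] = has_high
    return variants, flags


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

def simulate_codon_pairs(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> Tuple[List[Tuple[str, str]], float]:
    """Evolve codon-aligned sequence pairs at a known omega.

    An ancestor of ``n_codons`` sense codons is drawn uniformly; each of
    the two descendant lineages receives Poisson(3L * divergence / 2)
    proposed single-nucleotide changes at uniform positions; a proposal
    is rejected if it creates a stop, accepted if synonymous, and
    accepted with probability omega if nonsynonymous.
    """
    from .selection import SENSE_CODONS, STOP_CODONS, _AA

    if cfg.omega < 0 or cfg.divergence < 0:
        raise ValueError("omega and divergence must be >= 0")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    nucs = "ACGT"
    pairs: List[Tuple[str, str]] = []
    for _ in range(cfg.n_pairs):
        ancestor = [
            SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
            for _ in range(cfg.n_codons)
        ]

        def evolve(codons: List[str]) -> str:
            seq = list(codons)
            n_prop = rng.poisson(3 * cfg.n_codons * cfg.divergence / 2.0)
            for _ in range(n_prop):
                site = int(rng.integers(3 * cfg.n_codons))
                ci, off = divmod(site, 3)
                codon = seq[ci]
                new = nucs[int(rng.integers(4))]
                if new == codon[off]:
                    continue
                mutated = codon[:off] + new + codon[off + 1 :]
                if mutated in STOP_CODONS:
                    continue
                if _AA[codon] != _AA[mutated] and rng.random() >= cfg.omega:
                    continue
                seq[ci] = mutated
            return "".join(seq)

        pairs.append((evolve(ancestor), evolve(ancestor)))
    return pairs, cfg.omega


# ---------------------------------------------------------------------------
# targeted designs for calibration and association recovery
# ---------------------------------------------------------------------------

def simulate_pair_association_contig(
    seed: int,
    n_in: int = 500,
    n_out: int = 500,
    p_in: float = 0.5,
    p_out: float = 0.2,
    focal: Tuple[str, str] = ("RM", "CBASS"),
    filler: Tuple[str, ...] = ("Gabija", "Hachiman", "Thoeris", "Zorya"),
    other: Tuple[str, str] = ("Lamassu", "Septu"),
) -> Tuple[List[GeneRecord], List[DefenseAnnotation], float]:
    """One contig with a planted inside/outside family-pair association.

    ``n_in`` island structures each contain exactly one qualifying close
    pair; ``n_out`` isolated two-gene structures contribute outside
    pairs.  The qualifying pair carries the focal family pair with
    probability ``p_in`` inside and ``p_out`` outside, giving a true
    odds ratio of (p_in/(1-p_in)) / (p_out/(1-p_out)).
    """
    rng = np.random.default_rng(seed)
    true_or = (p_in / (1 - p_in)) / (p_out / (1 - p_out))
    structures = ["in"] * n_in + ["out"] * n_out
    rng.shuffle(structures)

    genes: List[GeneRecord] = []
    hits: List[DefenseAnnotation] = []
    ordinal = 0
    pos = 1
    contig = "assoc_c0"

    def add_gene(is_defense: bool, family: Optional[str]) -> None:
        nonlocal ordinal, pos
        length = 900
        g = GeneRecord(
            mag_id="assocMAG",
            contig_id=contig,
            gene_id=f"{contig}_g{ordinal:06d}",
            start=pos,
            end=pos + length - 1,
            strand="+",
            ordinal=ordinal,
        )
        genes.append(g)
        if is_defense and family is not None:
            hits.append(
                DefenseAnnotation(
                    gene_id=g.gene_id,
                    family=family,
                    gene_name=f"{family}_p1",
                    role="mandatory",
                )
            )
        ordinal += 1
        pos += length + 100

    def add_filler(n: int) -> None:
        for _ in range(n):
            add_gene(False, None)

    def focal_or_other(p: float) -> Tuple[str, str]:
        if rng.random() < p:
            return focal
        return other

    for kind in structures:
        add_filler(12)  # keep structures independent (> gap_max apart)
        if kind == "in":
            fa, fb = focal_or_other(p_in)
            # island of 6 defense units; only units 3-4 form a close pair
            add_gene(True, filler[0]); add_filler(6)
            add_gene(True, filler[1]); add_filler(6)
            add_gene(True, fa); add_filler(2)
            add_gene(True, fb); add_filler(6)
            add_gene(True, filler[2]); add_filler(6)
            add_gene(True, filler[3])
        else:
            fa, fb = focal_or_other(p_out)
            add_gene(True, fa); add_filler(2)
            add_gene(True, fb)
    add_filler(12)
    return genes, hits, true_or


def simulate_island_null_contig(
    seed: int,
    n_island_structures: int = 100,
    n_outside_structures: int = 100,
    families: Tuple[str, ...] = ("RM", "CBASS", "Gabija", "Hachiman", "Thoeris", "Zorya"),
) -> Tuple[List[GeneRecord], List[DefenseAnnotation]]:
    """A contig whose island geometry is fixed *before* families are drawn
    i.i.d., so family labels are independent of in/out island status (a
    clean enrichment null).

    Island structures hold 6 defense genes with internal gaps 6,6,2,6,6:
    they satisfy the island unit/gap rule and contribute exactly one
    qualifying close pair (<= 5 intervening genes).  Outside structures
    are isolated two-gene close pairs (never islands).  Structures are
    separated by 12 filler genes so no two interact, and qualifying pairs
    never share a gene.
    """
    rng = np.random.default_rng(seed)
    genes: List[GeneRecord] = []
    defense_flags: List[bool] = []
    ordinal = 0
    pos = 1
    contig = "null_c0"

    def add_gene(is_defense: bool) -> None:
        nonlocal ordinal, pos
        g = GeneRecord(
            mag_id="nullMAG",
            contig_id=contig,
            gene_id=f"{contig}_g{ordinal:06d}",
            start=pos,
            end=pos + 899,
            strand="+",
            ordinal=ordinal,
        )
        genes.append(g)
        defense_flags.append(is_defense)
        ordinal += 1
        pos += 1000

    def add_filler(n: int) -> None:
        for _ in range(n):
            add_gene(False)

    structures = ["island"] * n_island_structures + ["outside"] * n_outside_structures
    rng.shuffle(structures)
    for kind in structures:
        add_filler(12)
        if kind == "island":
            add_gene(True); add_filler(6)
            add_gene(True); add_filler(6)
            add_gene(True); add_filler(2)
            add_gene(True); add_filler(6)
            add_gene(True); add_filler(6)
            add_gene(True)
        else:
            add_gene(True); add_filler(2)
            add_gene(True)
    add_filler(12)

    hits = []
    for g, is_def in zip(genes, defense_flags):
        if not is_def:
            continue
        fam = str(rng.choice(families))
        hits.append(
            DefenseAnnotation(
                gene_id=g.gene_id, family=fam, gene_name=f"{fam}_p1", role="mandatory"
            )
        )
    return genes, hits


def simulate_mge_context_null(
    seed: int,
    n_genes: int = 800,
    families: Tuple[str, ...] = ("RM", "CBASS", "Gabija", "Hachiman", "Thoeris"),
    context_probs: Mapping[str, float] = None,
) -> Tuple[List[DefenseAnnotation], Dict[str, str]]:
    """Defense genes with MGE context labels drawn independently of
    family: the null of the family x context O/E chi-square test."""
    if context_probs is None:
        context_probs = {
            "chromosome": 0.70, "plasmid": 0.12, "prophage": 0.10, "ICE_IME": 0.08
        }
    rng = np.random.default_rng(seed)
    contexts = sorted(context_probs)
    probs = [context_probs[c] for c in contexts]
    hits: List[DefenseAnnotation] = []
    labels: Dict[str, str] = {}
    for i in range(n_genes):
        gid = f"nullmge_g{i:05d}"
        fam = str(rng.choice(families))
        hits.append(
            DefenseAnnotation(
                gene_id=gid, family=fam, gene_name=f"{fam}_p1", role="mandatory"
            )
        )
        labels[gid] = str(rng.choice(contexts, p=probs))
    return hits, labels
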