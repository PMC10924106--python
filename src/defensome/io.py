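"""Readers and writers for every format the pipeline consumes or emits.

Supported inputs: gene tables (GFF3 or TSV), defense-gene annotation TSV
(DefenseFinder-style columns), MGE interval BED, variant tables (VCF or
TSV), MAG metadata TSV and Newick trees.  All writers emit TSV with a
commented header line stating column semantics.

Internally every coordinate is 1-based inclusive; BED (0-based half-open)
is converted at this boundary.
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy

from .types import (
    MGE_CLASSES,
    DefenseAnnotation,
    GeneRecord,
    MAGRecord,
    MGEInterval,
    VariantRecord,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_GENE_TSV_COLUMNS = ["mag_id", "contig_id", "gene_id", "start", "end", "strand"]


def assign_ordinals(
    raw: Sequence[Tuple[str, str, str, int, int, str]]
) -> List[GeneRecord]:
    """Build GeneRecords with per-contig ordinals.

    Genes are sorted within each contig by ascending start; ties are broken
    by ascending end, then lexicographic gene_id, so output is deterministic
    for overlapping/nested genes.
    """
    seen: set = set()
    for mag_id, contig_id, gene_id, start, end, strand in raw:
        if gene_id in seen:
            raise ParseError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)

    by_contig: Dict[Tuple[str, str], list] = defaultdict(list)
    for row in raw:
        by_contig[(row[0], row[1])].append(row)

    records: List[GeneRecord] = []
    for key in sorted(by_contig):
        rows = sorted(by_contig[key], key=lambda r: (r[3], r[4], r[2]))
        for ordinal, (mag_id, contig_id, gene_id, start, end, strand) in enumerate(rows):
            records.append(
                GeneRecord(
                    mag_id=mag_id,
                    contig_id=contig_id,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    ordinal=ordinal,
                )
            )
    return records


def _read_gene_tsv(path: Path) -> List[GeneRecord]:
    raw = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[List[str]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                missing = [c for c in _GENE_TSV_COLUMNS if c not in header]
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: gene TSV missing columns {missing}"
                    )
                idx = {c: header.index(c) for c in _GENE_TSV_COLUMNS}
                continue
            try:
                raw.append(
                    (
                        row[idx["mag_id"]],
                        row[idx["contig_id"]],
                        row[idx["gene_id"]],
                        int(row[idx["start"]]),
                        int(row[idx["end"]]),
                        row[idx["strand"]],
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed gene row ({exc})") from exc
    try:
        return assign_ordinals(raw)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _gff_attributes(field: str) -> Dict[str, str]:
    out = {}
    for part in field.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gene_gff3(path: Path, mag_id: Optional[str]) -> List[GeneRecord]:
    mag = mag_id if mag_id is not None else Path(path).stem
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] not in ("gene", "CDS"):
                continue
            attrs = _gff_attributes(fields[8])
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: feature without ID attribute")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            raw.append((mag, fields[0], gene_id, start, end, fields[6]))
    try:
        return assign_ordinals(raw)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_gene_table(path, mag_id: Optional[str] = None) -> List[GeneRecord]:
    """Read a gene table in GFF3 (``.gff``/``.gff3`` or ``##gff-version``
    header) or TSV dialect and assign per-contig ordinals."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gene_gff3(path, mag_id)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff-version"):
        return _read_gene_gff3(path, mag_id)
    return _read_gene_tsv(path)


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene table: 1-based inclusive coordinates; strand in {+,-}\n")
        fh.write("\t".join(_GENE_TSV_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.mag_id}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# defense annotations
# ---------------------------------------------------------------------------

def read_defense_annotations(path) -> List[DefenseAnnotation]:
    """Read DefenseFinder-style hits: gene_id, family, gene_name, role
    and optional system_id.  A gene carries at most one annotation: on
    duplicate gene_id rows the first wins and a warning is emitted."""
    path = Path(path)
    annotations: List[DefenseAnnotation] = []
    seen: set = set()
    n_dupes = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                required = ["gene_id", "family", "gene_name", "role"]
                missing = [c for c in required if c not in header]
                if missing:
                    raise ParseError(f"{path}:{lineno}: missing columns {missing}")
                idx = {c: header.index(c) for c in header}
                continue
            gene_id = row[idx["gene_id"]]
            if gene_id in seen:
                n_dupes += 1
                continue
            seen.add(gene_id)
            family = row[idx["family"]]
            if not family:
                raise ParseError(f"{path}:{lineno}: missing family for {gene_id}")
            role = row[idx["role"]].strip().lower()
            if role not in ("mandatory", "accessory"):
                raise ParseError(
                    f"{path}:{lineno}: unknown role {row[idx['role']]!r} "
                    "(expected mandatory/accessory)"
                )
            system_id = None
            if "system_id" in idx and len(row) > idx["system_id"]:
                system_id = row[idx["system_id"]] or None
            annotations.append(
                DefenseAnnotation(
                    gene_id=gene_id,
                    family=family,
                    gene_name=row[idx["gene_name"]],
                    role=role,
                    system_id=system_id,
                )
            )
    if n_dupes:
        warnings.warn(
            f"{path}: {n_dupes} duplicate defense hit(s) dropped (first kept)",
            stacklevel=2,
        )
    return annotations


def write_defense_annotations(annotations: Iterable[DefenseAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("# defense hits: one row per gene; role in {mandatory,accessory}\n")
        fh.write("gene_id\tfamily\tgene_name\trole\tsystem_id\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.family}\t{a.gene_name}\t{a.role}\t{a.system_id or ''}\n"
            )


# ---------------------------------------------------------------------------
# MGE intervals
# ---------------------------------------------------------------------------

def _merge_same_class(intervals: List[MGEInterval]) -> List[MGEInterval]:
    """Union-merge overlapping/nested intervals of the same class."""
    merged: List[MGEInterval] = []
    by_key: Dict[Tuple[str, str], List[MGEInterval]] = defaultdict(list)
    for iv in intervals:
        by_key[(iv.contig_id, iv.mge_class)].append(iv)
    for (contig, cls), ivs in sorted(by_key.items()):
        ivs = sorted(ivs, key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(MGEInterval(contig, cur_start, cur_end, cls))
                cur_start, cur_end = iv.start, iv.end
        merged.append(MGEInterval(contig, cur_start, cur_end, cls))
    return merged


def filter_mge_conflicts(intervals: Sequence[MGEInterval]) -> List[MGEInterval]:
    """Drop every interval that overlaps (>= 1 bp) an interval of a
    *different* class, mirroring the exclusion of ambiguous multi-family
    MGE hits.  Same-class overlaps are union-merged first."""
    merged = _merge_same_class(list(intervals))
    keep = []
    n_removed = 0
    for iv in merged:
        if any(
            iv.overlaps(other) and other.mge_class != iv.mge_class for other in merged
        ):
            n_removed += 1
        else:
            keep.append(iv)
    if n_removed:
        warnings.warn(
            f"{n_removed} MGE interval(s) removed due to cross-class overlap",
            stacklevel=2,
        )
    return keep


def read_mge_intervals(path, conflict_filter: bool = True) -> List[MGEInterval]:
    """Read a BED file (0-based half-open, class label in column 4),
    convert to 1-based inclusive, and apply the cross-class conflict
    filter."""
    path = Path(path)
    intervals: List[MGEInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns")
            cls = fields[3]
            if cls not in MGE_CLASSES:
                raise ParseError(
                    f"{path}:{lineno}: unknown MGE class {cls!r}; "
                    f"allowed: {', '.join(MGE_CLASSES)}"
                )
            start0, end0 = int(fields[1]), int(fields[2])
            intervals.append(MGEInterval(fields[0], start0 + 1, end0, cls))
    if conflict_filter:
        intervals = filter_mge_conflicts(intervals)
    return intervals


def write_mge_bed(intervals: Iterable[MGEInterval], path) -> None:
    """Write intervals back to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start - 1}\t{iv.end}\t{iv.mge_class}\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "gene_id",
    "position",
    "var_type",
    "region",
    "allele_frequency",
    "supporting_reads",
]


def _read_variants_vcf(path: Path) -> List[VariantRecord]:
    from cyvcf2 import VCF

    records: List[VariantRecord] = []
    n_skipped = 0
    for rec in VCF(str(path)):
        dp = rec.INFO.get("DP")
        ao = rec.INFO.get("AO")
        af = rec.INFO.get("AF")
        alts = rec.ALT or []
        for i, alt in enumerate(alts):
            if isinstance(ao, tuple):
                ao_i = ao[i]
            else:
                ao_i = ao
            if isinstance(af, tuple):
                af_i = af[i]
            else:
                af_i = af
            if af_i is None:
                if dp in (None, 0):
                    n_skipped += 1
                    continue
                af_i = float(ao_i) / float(dp)
            reads = int(ao_i) if ao_i is not None else (int(dp) if dp else 0)
            var_type = "SNP_unclassified" if len(rec.REF) == len(alt) else "indel"
            records.append(
                VariantRecord(
                    gene_id=rec.CHROM,
                    position=rec.POS,
                    var_type=var_type,
                    region="unassigned",
                    allele_frequency=float(af_i),
                    supporting_reads=reads,
                )
            )
    if n_skipped:
        warnings.warn(f"{path}: {n_skipped} VCF record(s) with DP=0 skipped", stacklevel=2)
    return records


def _read_variants_tsv(path: Path) -> List[VariantRecord]:
    records: List[VariantRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                missing = [
                    c
                    for c in ("gene_id", "position", "allele_frequency", "supporting_reads")
                    if c not in header
                ]
                if missing:
                    raise ParseError(f"{path}:{lineno}: missing columns {missing}")
                idx = {c: header.index(c) for c in header}
                continue
            try:
                records.append(
                    VariantRecord(
                        gene_id=row[idx["gene_id"]],
                        position=int(row[idx["position"]]),
                        var_type=row[idx["var_type"]]
                        if "var_type" in idx
                        else "SNP_unclassified",
                        region=row[idx["region"]] if "region" in idx else "unassigned",
                        allele_frequency=float(row[idx["allele_frequency"]]),
                        supporting_reads=int(row[idx["supporting_reads"]]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed variant row ({exc})") from exc
    return records


def read_variants(path) -> List[VariantRecord]:
    """Read variants from VCF (one record per ALT allele; frequency from
    AF, or AO/DP when AF is absent) or from an explicit TSV."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _read_variants_vcf(path)
    return _read_variants_tsv(path)


def write_variants_tsv(variants: Iterable[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# variants: position is 1-based within the analyzed region; "
            "allele_frequency in [0,1]\n"
        )
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                f"{v.gene_id}\t{v.position}\t{v.var_type}\t{v.region}\t"
                f"{v.allele_frequency:.6g}\t{v.supporting_reads}\n"
            )


# ---------------------------------------------------------------------------
# MAG metadata
# ---------------------------------------------------------------------------

def read_mag_metadata(path) -> List[MAGRecord]:
    mags: List[MAGRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                idx = {c: header.index(c) for c in header}
                continue
            contig_lengths = tuple(
                int(x) for x in row[idx["contig_lengths"]].split(",") if x
            )
            rrna = frozenset(x for x in row[idx["rrna_classes"]].split(",") if x)
            mags.append(
                MAGRecord(
                    mag_id=row[idx["mag_id"]],
                    habitat=row[idx["habitat"]],
                    sub_habitat=row[idx["sub_habitat"]] if "sub_habitat" in idx else "",
                    size_bp=int(row[idx["size_bp"]]),
                    completeness=float(row[idx["completeness"]]),
                    contamination=float(row[idx["contamination"]]),
                    trna_count=int(row[idx["trna_count"]]),
                    rrna_classes=rrna,
                    contig_lengths=contig_lengths,
                    n50=int(row[idx["n50"]]) if "n50" in idx and row[idx["n50"]] else None,
                )
            )
    return mags


def write_mag_metadata(mags: Iterable[MAGRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# MAG metadata: completeness/contamination in %, sizes in bp; "
            "rrna_classes and contig_lengths comma-separated\n"
        )
        fh.write(
            "mag_id\thabitat\tsub_habitat\tsize_bp\tcompleteness\tcontamination\t"
            "trna_count\trrna_classes\tcontig_lengths\tn50\n"
        )
        for m in mags:
            rrna = ",".join(sorted(m.rrna_classes))
            lengths = ",".join(str(x) for x in m.contig_lengths)
            fh.write(
                f"{m.mag_id}\t{m.habitat}\t{m.sub_habitat}\t{m.size_bp}\t"
                f"{m.completeness!r}\t{m.contamination!r}\t{m.trna_count}\t"
                f"{rrna}\t{lengths}\t{m.n50 if m.n50 is not None else ''}\n"
            )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return tree
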