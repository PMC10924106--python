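"""Shared builders for small hand-laid genomes used across the suite."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import pytest
from hypothesis import settings

from defensome.types import DefenseAnnotation, GeneRecord

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_contig(
    n_genes: int,
    contig_id: str = "c0",
    mag_id: str = "magA",
    gene_length: int = 900,
    spacing: int = 100,
    strand: str = "+",
) -> List[GeneRecord]:
    """A contig of evenly spaced genes; ordinal i sits at start
    1 + i*(gene_length+spacing)."""
    genes = []
    for i in range(n_genes):
        start = 1 + i * (gene_length + spacing)
        genes.append(
            GeneRecord(
                mag_id=mag_id,
                contig_id=contig_id,
                gene_id=f"{contig_id}_g{i:03d}",
                start=start,
                end=start + gene_length - 1,
                strand=strand,
                ordinal=i,
            )
        )
    return genes


def hits_at(
    genes: Sequence[GeneRecord],
    placements: Sequence[Tuple[int, str]],
    role: str = "mandatory",
    gene_names: Optional[Sequence[str]] = None,
    system_ids: Optional[Sequence[Optional[str]]] = None,
) -> List[DefenseAnnotation]:
    """Defense hits at (ordinal, family) placements on one contig."""
    out = []
    for k, (ordinal, family) in enumerate(placements):
        out.append(
            DefenseAnnotation(
                gene_id=genes[ordinal].gene_id,
                family=family,
                gene_name=gene_names[k] if gene_names else f"{family}_p1",
                role=role,
                system_id=system_ids[k] if system_ids else None,
            )
        )
    return out
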