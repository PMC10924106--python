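"""MAG quality gating: MIMAG-style completeness/contamination/RNA criteria
plus an assembly-contiguity (N50) filter.

Defaults mirror a high-quality draft gate: completeness >= 90%,
contamination <= 5%, >= 18 tRNAs, all of the 5S/16S/23S rRNA classes
present, and N50 >= 100 kb.  All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .types import MAGRecord, RRNA_CLASSES


@dataclass(frozen=True)
class QCThresholds:
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    min_trna: int = 18
    required_rrna: frozenset = frozenset(RRNA_CLASSES)
    min_n50: int = 100_000
    # MIMAG's rRNA wording can be read as "all three classes" (the
    # high-quality reading, default) or "any one class"
    require_all_rrna: bool = True

    def __post_init__(self) -> None:
        if min(self.min_completeness, self.max_contamination, self.min_trna, self.min_n50) < 0:
            raise ValueError("QC thresholds must be non-negative")


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """Contig length at which sorted-descending contigs cumulatively reach
    half the assembly size."""
    if not contig_lengths:
        raise ValueError("compute_n50: empty contig length list")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("compute_n50: contig lengths must be positive")
    total = sum(contig_lengths)
    acc = 0
    for length in sorted(contig_lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def mimag_filter(mag: MAGRecord, thresholds: QCThresholds = QCThresholds()) -> Tuple[bool, List[str]]:
    """Apply the quality gate to one MAG.

    Returns (passed, failed_criteria).  All thresholds inclusive; a MAG at
    exactly the boundary passes.  N50 is recomputed from contig lengths when
    not supplied in metadata.
    """
    failures: List[str] = []
    if mag.completeness is None or mag.contamination is None:
        raise ValueError(f"{mag.mag_id}: missing completeness/contamination")
    if mag.completeness < thresholds.min_completeness:
        failures.append("completeness")
    if mag.contamination > thresholds.max_contamination:
        failures.append("contamination")
    if mag.trna_count < thresholds.min_trna:
        failures.append("trna_count")
    present = mag.rrna_classes & thresholds.required_rrna
    if thresholds.require_all_rrna:
        if present != frozenset(thresholds.required_rrna):
            failures.append("rrna_classes")
    else:
        if not present:
            failures.append("rrna_classes")
    n50 = mag.n50
    if n50 is None:
        if not mag.contig_lengths:
            raise ValueError(f"{mag.mag_id}: no n50 and no contig lengths")
        n50 = compute_n50(mag.contig_lengths)
    if n50 < thresholds.min_n50:
        failures.append("n50")
    return (not failures, failures)


def filter_mags(
    mags: Sequence[MAGRecord], thresholds: QCThresholds = QCThresholds()
) -> Tuple[List[MAGRecord], List[Tuple[str, List[str]]]]:
    """Split a cohort into passing MAGs and (mag_id, failures) for the rest."""
    passed, failed = [], []
    for mag in mags:
        ok, failures = mimag_filter(mag, thresholds)
        if ok:
            passed.append(mag)
        else:
            failed.append((mag.mag_id, failures))
    return passed, failed
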