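"""Island calling against a brute-force enumerator, plus content stats."""

import numpy as np
import pytest

from defensome.islands import (
    call_islands,
    family_island_enrichment,
    island_summary,
    odds_ratio_2x2,
    skew_ratio,
)
from defensome.types import GeneStatus

from conftest import hits_at, make_contig
from oracles import brute_force_islands


class TestCallIslands:
    def test_reference_layout_single_island(self):
        genes = make_contig(20)
        placements = [(1, "A"), (2, "A"), (5, "B"), (9, "C"), (12, "A")]
        hits = hits_at(genes, placements)
        islands = call_islands(genes, hits, gap_max=3, min_units=5, min_families=3)
        (isl,) = islands
        assert (isl.first_ordinal, isl.last_ordinal) == (1, 12)
        assert isl.length_genes == 12
        assert isl.families == frozenset({"A", "B", "C"})

    def test_below_min_units_no_island(self):
        genes = make_contig(20)
        hits = hits_at(genes, [(1, "A"), (2, "B"), (3, "C"), (4, "A")])
        assert call_islands(genes, hits) == []

    def test_below_min_families_no_island(self):
        genes = make_contig(20)
        hits = hits_at(genes, [(i, "A") for i in range(1, 7)])
        assert call_islands(genes, hits) == []

    def test_unknown_family_counts_as_unit_not_family(self):
        genes = make_contig(20)
        hits = hits_at(genes, [(1, "A"), (2, "B"), (3, "unknown"), (4, "unknown"), (5, "C")])
        (isl,) = call_islands(genes, hits)
        assert isl.n_units == 5
        assert isl.families == frozenset({"A", "B", "C"})
        # but unknown hits do not rescue the family minimum
        hits2 = hits_at(genes, [(1, "A"), (2, "B")] + [(k, "unknown") for k in (3, 4, 5)])
        assert call_islands(genes, hits2) == []

    def test_islands_never_span_contigs(self):
        c0 = make_contig(10, contig_id="c0")
        c1 = make_contig(10, contig_id="c1")
        hits = hits_at(c0, [(7, "A"), (8, "B"), (9, "C")]) + hits_at(
            c1, [(0, "A"), (1, "B")]
        )
        assert call_islands(c0 + c1, hits) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_contigs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 61))
        genes = make_contig(n)
        n_def = int(rng.integers(0, min(20, n)))
        ordinals = sorted(rng.choice(n, size=n_def, replace=False).tolist())
        fams = [
            str(rng.choice(["A", "B", "C", "D", "unknown"])) for _ in range(n_def)
        ]
        hits = hits_at(genes, list(zip(ordinals, fams)))
        got = call_islands(genes, hits, gap_max=4, min_units=3, min_families=2)
        want = brute_force_islands(ordinals, fams, gap_max=4, min_units=3, min_families=2)
        assert [(i.first_ordinal, i.last_ordinal) for i in got] == [
            (w[0], w[1]) for w in want
        ]
        for isl, w in zip(got, want):
            member_ordinals = tuple(
                sorted(int(g.split("_g")[1]) for g in isl.member_gene_ids)
            )
            assert member_ordinals == w[2]

    def test_maximality_cannot_extend(self):
        genes = make_contig(40)
        placements = [(5, "A"), (6, "B"), (7, "C"), (8, "A"), (9, "B")]
        hits = hits_at(genes, placements + [(25, "C")])  # far unit: gap 15 > 10
        (isl,) = call_islands(genes, hits)
        assert isl.last_ordinal == 9  # distant unit not absorbed

    def test_system_mode_counts_systems(self):
        from defensome.assembly import assemble_systems

        genes = make_contig(40)
        # five single-gene families -> five singleton systems close together
        placements = [(3, "A"), (5, "B"), (7, "C"), (9, "D"), (11, "E")]
        hits = hits_at(genes, placements)
        systems, _ = assemble_systems(genes, hits)
        (isl,) = call_islands(genes, hits, systems=systems, unit="system")
        assert isl.counting_unit == "system"
        assert isl.n_units == 5


class TestSummaries:
    def test_content_fraction_of_reference_layout(self):
        genes = make_contig(20)
        hits = hits_at(genes, [(1, "A"), (2, "A"), (5, "B"), (9, "C"), (12, "A")])
        islands = call_islands(genes, hits, gap_max=3)
        s = island_summary(islands, genes, hits)
        assert s["defense_content_fraction"] == pytest.approx(5 / 12)
        assert s["median_length_genes"] == 12

    def test_density_arithmetic(self):
        genes = make_contig(30, mag_id="magA")
        hits = hits_at(genes, [(1, "A"), (2, "B"), (3, "C"), (4, "A"), (5, "B")])
        islands = call_islands(genes, hits)
        from defensome.types import MAGRecord

        mag = MAGRecord(
            mag_id="magA", habitat="soil", size_bp=4_000_000,
            completeness=95, contamination=1, trna_count=20,
            rrna_classes=frozenset({"5S", "16S", "23S"}),
            contig_lengths=(4_000_000,),
        )
        s = island_summary(islands, genes, hits, [mag])
        assert s["density_per_mag_per_kb"]["magA"] == pytest.approx(
            len(islands) / 4000.0
        )

    def test_zero_islands_empty_distribution(self):
        genes = make_contig(10)
        s = island_summary([], genes, [])
        assert s["n_islands"] == 0 and s["lengths_genes"] == []


class TestSkewRatio:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            ([GeneStatus.COMPLETE] * 4, 1.0),
            ([GeneStatus.COMPLETE] * 3 + [GeneStatus.INCOMPLETE], 0.5),
            ([GeneStatus.COMPLETE] * 2 + [GeneStatus.INCOMPLETE] * 2, 0.0),
        ],
    )
    def test_known_values(self, statuses, expected):
        assert skew_ratio(statuses) == pytest.approx(expected)

    def test_solitary_counted_incomplete_by_default(self):
        statuses = [GeneStatus.COMPLETE] * 3 + [GeneStatus.SOLITARY]
        assert skew_ratio(statuses) == pytest.approx(0.5)
        assert skew_ratio(statuses, include_solitary=False) == pytest.approx(1.0)

    def test_undefined_when_empty(self):
        assert skew_ratio([]) is None


class TestEnrichment:
    def test_hand_computed_odds_ratio(self):
        assert odds_ratio_2x2(20, 80, 10, 890) == pytest.approx(22.25)

    def test_haldane_correction_on_zero_cell(self):
        assert odds_ratio_2x2(0, 10, 5, 5) == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5)
        )

    def test_balanced_counts_give_or_one_p_one(self):
        genes = make_contig(120)
        # island: ordinals 10-14; equal family mix inside and outside,
        # outside genes isolated (> 10 intervening) so no second island
        inside = [(10, "A"), (11, "B"), (12, "C"), (13, "A"), (14, "B")]
        outside = [(30, "A"), (42, "B"), (54, "C"), (66, "A"), (78, "B")]
        hits = hits_at(genes, inside + outside)
        islands = call_islands(genes, hits)
        rows = family_island_enrichment(genes, hits, islands)
        for row in rows:
            assert row["odds_ratio"] == pytest.approx(1.0)
            assert row["p"] == pytest.approx(1.0)
        assert all(0 <= r["q"] <= 1 for r in rows)
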