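"""High-frequency filtering, region/type classification, family O/E."""

import numpy as np
import pytest

from defensome.types import GeneRecord, GeneVariantSummary, VariantRecord
from defensome.variants import (
    classify_variant,
    family_variant_oe,
    filter_high_frequency,
    summarize_gene_variants,
    upstream_window,
)


def variant(pos, freq=0.5, reads=20, var_type="SNP_unclassified", gene_id="g1"):
    return VariantRecord(
        gene_id=gene_id, position=pos, var_type=var_type,
        region="unassigned", allele_frequency=freq, supporting_reads=reads,
    )


def gene(start=1000, end=1899, strand="+", gene_id="g1"):
    return GeneRecord(
        mag_id="m", contig_id="c", gene_id=gene_id,
        start=start, end=end, strand=strand, ordinal=0,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "freq,reads,kept",
        [
            (0.30, 12, True),
            (0.30, 9, False),
            (0.20, 50, False),
            (0.25, 10, True),  # boundaries inclusive
            (0.2499, 10, False),
        ],
    )
    def test_threshold_semantics(self, freq, reads, kept):
        out = filter_high_frequency([variant(100, freq, reads)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert filter_high_frequency([]) == []


class TestClassification:
    def test_upstream_window_plus_strand(self):
        g = gene(start=1000, end=1899, strand="+")
        assert upstream_window(g) == (800, 999)
        v = classify_variant(variant(850), g)
        assert v.region == "upstream"

    def test_upstream_window_minus_strand_is_reflected(self):
        g = gene(start=1000, end=1899, strand="-")
        assert upstream_window(g) == (1900, 2099)
        assert classify_variant(variant(1950), g).region == "upstream"
        assert classify_variant(variant(1500), g).region == "gene_body"

    def test_outside_analyzed_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_variant(variant(500), gene(start=1000, end=1899))

    def test_synonymous_third_position(self):
        # codon TTT at gene start; third-position T->C gives TTC (Phe)
        g = gene(start=1000, end=1899, strand="+")
        cds = "TTT" + "A" * 897
        v = classify_variant(variant(1002), g, cds_sequence=cds, ref_base="T", alt_base="C")
        assert v.var_type == "SNP_synonymous"

    def test_nonsynonymous_first_position(self):
        g = gene(start=1000, end=1899, strand="+")
        cds = "TTT" + "A" * 897
        v = classify_variant(variant(1000), g, cds_sequence=cds, ref_base="T", alt_base="C")
        assert v.var_type == "SNP_nonsynonymous"  # CTT = Leu

    def test_minus_strand_alleles_complemented(self):
        # minus-strand gene: contig end corresponds to CDS start.
        g = gene(start=1000, end=1899, strand="-")
        cds = "TTT" + "A" * 897
        # CDS position 2 (third codon base) sits at contig 1897;
        # contig A->G reads as complemented T->C on the coding strand
        v = classify_variant(variant(1897), g, cds_sequence=cds, ref_base="A", alt_base="G")
        assert v.var_type == "SNP_synonymous"

    def test_indel_keeps_type(self):
        g = gene()
        v = classify_variant(variant(1100, var_type="indel"), g)
        assert v.var_type == "indel" and v.region == "gene_body"

    def test_strand_mirror_preserves_classification(self):
        """Mirroring the gene to the minus strand maps each variant to the
        reflected coordinate with identical region and type."""
        g_plus = gene(start=1000, end=1899, strand="+")
        g_minus = gene(start=1000, end=1899, strand="-")
        cds = ("ATGGCTAAATTTCCC" * 60)[:900]
        for cds_pos in (0, 1, 2, 10, 450, 899):
            contig_plus = 1000 + cds_pos
            contig_minus = 1899 - cds_pos
            ref = cds[cds_pos]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            v_plus = classify_variant(
                variant(contig_plus), g_plus, cds_sequence=cds, ref_base=ref, alt_base=alt
            )
            v_minus = classify_variant(
                variant(contig_minus), g_minus, cds_sequence=cds,
                ref_base=comp[ref], alt_base=comp[alt],
            )
            assert v_plus.var_type == v_minus.var_type
            assert v_plus.region == v_minus.region == "gene_body"


class TestSummaries:
    def test_fractions_sum_to_one(self):
        g = gene()
        vs = [
            classify_variant(variant(1100), g),
            classify_variant(variant(850, var_type="indel"), g),
            classify_variant(variant(1500), g),
        ]
        s = summarize_gene_variants(g, "RM", vs)
        assert sum(s.type_fractions.values()) == pytest.approx(1.0)
        assert sum(s.region_fractions.values()) == pytest.approx(1.0)
        assert s.n_snp == 2 and s.n_indel == 1
        assert s.analyzed_length_bp == 900 + 200
        assert s.density_per_kb == pytest.approx(3 / 1.1)

    def test_no_variants_not_flagged(self):
        s = summarize_gene_variants(gene(), "RM", [])
        assert not s.has_high_frequency_variant and s.density_per_kb == 0


def summary(gene_id, family, flagged):
    s = GeneVariantSummary(gene_id=gene_id, family=family, analyzed_length_bp=1100)
    s.has_high_frequency_variant = flagged
    return s


class TestFamilyOE:
    def test_oe_formula(self):
        # family F: 100 genes, 30 flagged; family G: 100 genes, 10 flagged
        # overall fraction 0.2 -> E = 20 per family; F O/E = 1.5
        summaries = (
            [summary(f"f{i}", "F", i < 30) for i in range(100)]
            + [summary(f"g{i}", "G", i < 10) for i in range(100)]
        )
        res = family_variant_oe(summaries)
        cell_f = next(c for c in res["cells"] if c.family == "F")
        assert res["overall_fraction"] == pytest.approx(0.2)
        assert cell_f.expected == pytest.approx(20.0)
        assert cell_f.oe == pytest.approx(1.5)
        assert res["highlighted"] == ["F"]

    def test_small_family_excluded(self):
        summaries = [summary(f"f{i}", "F", i < 3) for i in range(20)] + [
            summary(f"g{i}", "G", False) for i in range(9)
        ]
        res = family_variant_oe(summaries)
        assert res["excluded_families"] == ["G"]

    def test_expected_sums_match_observed(self):
        rng = np.random.default_rng(0)
        summaries = [
            summary(f"{fam}{i}", fam, bool(rng.random() < 0.3))
            for fam in "FGH"
            for i in range(40)
        ]
        res = family_variant_oe(summaries)
        assert sum(c.expected for c in res["cells"]) == pytest.approx(
            sum(c.observed for c in res["cells"])
        )

    def test_null_mean_oe_near_one(self):
        rng = np.random.default_rng(1)
        oes = []
        for _ in range(300):
            summaries = [
                summary(f"{fam}{i}", fam, bool(rng.random() < 0.25))
                for fam in "FG"
                for i in range(50)
            ]
            res = family_variant_oe(summaries)
            oes.extend(c.oe for c in res["cells"] if np.isfinite(c.oe))
        assert np.mean(oes) == pytest.approx(1.0, abs=0.05)
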