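"""Recessive filter vs truth-table oracle; CDS mapping and HGVS naming."""

import itertools

import pytest

from autozygmap.filtering import (FilterPolicy, annotate_consequences,
                                  annotate_region, cds_position, complement,
                                  consequence_of, filter_recessive_private,
                                  genomic_position, protein_changing)
from autozygmap.io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                           TranscriptModel, VariantRecord)
from autozygmap.roh import SharedRegion

STATES = (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING)


def variant(gts, pos=100):
    return VariantRecord("1", pos, "G", "A", genotypes=dict(gts))


class TestRecessiveFilter:
    def test_truth_table_all_assignments(self):
        """Every genotype assignment for 2 cases + 2 controls agrees with the
        direct truth-table definition (case hom-alt required, control hom-alt
        forbidden, missing case fails, missing control ignored)."""
        policy = FilterPolicy(("c1", "c2"), ("k1", "k2"))
        for a in itertools.product(STATES, repeat=4):
            gts = dict(zip(("c1", "c2", "k1", "k2"), a))
            survives = bool(filter_recessive_private([variant(gts)], policy))
            expect = (a[0] == GT_HOM_ALT and a[1] == GT_HOM_ALT
                      and a[2] != GT_HOM_ALT and a[3] != GT_HOM_ALT)
            assert survives == expect, gts

    def test_study_shaped_pass(self):
        cases = {f"case{i}": GT_HOM_ALT for i in range(3)}
        controls = {f"k{i}": (GT_HET if i % 10 == 0 else GT_HOM_REF)
                    for i in range(567)}
        policy = FilterPolicy(tuple(cases), tuple(controls))
        assert filter_recessive_private([variant({**cases, **controls})], policy)

    def test_monotone_in_controls(self):
        """Adding a control can only remove variants, never add."""
        cases = {"c1": GT_HOM_ALT}
        v1 = variant({**cases, "k1": GT_HET}, pos=10)
        v2 = variant({**cases, "k1": GT_HET, "k2": GT_HOM_ALT}, pos=20)
        small = filter_recessive_private([v1, v2], FilterPolicy(("c1",), ("k1",)))
        big = filter_recessive_private([v1, v2], FilterPolicy(("c1",), ("k1", "k2")))
        assert {v.pos_bp for v in big} <= {v.pos_bp for v in small}

    def test_order_preserved(self):
        cases = {"c1": GT_HOM_ALT}
        vs = [variant({**cases, "k1": GT_HOM_REF}, pos=p) for p in (5, 3, 9)]
        out = filter_recessive_private(vs, FilterPolicy(("c1",), ("k1",)))
        assert [v.pos_bp for v in out] == [5, 3, 9]

    def test_empty_cases_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy((), ("k1",))


class TestRegionAnnotation:
    def test_boundaries_closed(self):
        region = SharedRegion("14", 74_306_245, 76_800_429, 28, True)
        inside = VariantRecord("14", 76_011_964, "G", "A")
        at_start = VariantRecord("14", 74_306_245, "G", "A")
        below = VariantRecord("14", 74_306_244, "G", "A")
        other = VariantRecord("11", 76_011_964, "G", "A")
        annotate_region([inside, at_start, below, other], [region])
        key = "14:74306245-76800429"
        assert inside.region_flags[key]
        assert at_start.region_flags[key]
        assert not below.region_flags[key]
        assert not other.region_flags[key]


def plus_transcript():
    # single exon, CDS 1001..1000+2430
    return TranscriptModel("g", "1", "+", [(901, 3600)], 1001, 3430)


def minus_transcript():
    # two exons, CDS read from the right
    return TranscriptModel("g", "1", "-", [(1001, 2200), (5001, 6230)],
                           1001, 6230)


class TestCdsMapping:
    def test_plus_strand_offset(self):
        """cds_start at g.1001 puts g.1751 at c.751."""
        assert cds_position(1751, plus_transcript()) == 751
        assert cds_position(1000, plus_transcript()) is None   # 5' of CDS

    def test_minus_strand_two_exon_hand_computed(self):
        t = minus_transcript()
        # minus strand: c.1 = g.6230; exon2 holds c.1..1230, exon1 c.1231..2430
        assert cds_position(6230, t) == 1
        assert cds_position(5001, t) == 1230
        assert cds_position(2200, t) == 1231
        assert cds_position(2200 - 750, t) == 1981
        assert cds_position(3000, t) is None                   # intronic

    @pytest.mark.parametrize("transcript", [plus_transcript(), minus_transcript()])
    def test_roundtrip_both_strands(self, transcript):
        for c in (1, 2, 3, 751, transcript.cds_length()):
            assert cds_position(genomic_position(c, transcript), transcript) == c


class TestConsequence:
    def test_asp251asn(self):
        """c.751G>A in a GAT codon: codon 251, Asp -> Asn."""
        cds = "ATG" + "GCT" * 249 + "GAT" + "GCT" * 558 + "TAA"
        # codon 251 occupies cds positions 751-753
        assert cds[750:753] == "GAT"
        c = consequence_of(751, "G", "A", cds)
        assert c.codon_index == 251
        assert (c.ref_aa, c.alt_aa) == ("Asp", "Asn")
        assert c.klass == "missense"
        assert c.hgvs_c == "c.751G>A"
        assert c.hgvs_p == "p.Asp251Asn"

    def test_asp262asn(self):
        """c.784G>A in a GAC codon: codon 262 (the orthologous canine change)."""
        cds = "ATG" + "GCT" * 260 + "GAC" + "GCT" * 547 + "TAA"
        assert cds[783:786] == "GAC"
        c = consequence_of(784, "G", "A", cds)
        assert c.codon_index == 262
        assert c.hgvs_p == "p.Asp262Asn"

    def test_synonymous_and_nonsense(self):
        cds = "ATGGATTACTAA"          # Met-Asp-Tyr-stop
        syn = consequence_of(6, "T", "C", cds)     # GAT -> GAC, both Asp
        assert syn.klass == "synonymous" and syn.alt_aa == "Asp"
        non = consequence_of(7, "T", "A", cds)     # TAC -> AAC? no: pos7 T>A
        # TAC (Tyr) -> AAC (Asn) is missense; make a real stop: TAC -> TAA
        stop = consequence_of(9, "C", "A", cds)
        assert stop.klass == "nonsense" and stop.alt_aa == "Ter"
        assert non.klass == "missense"

    def test_reference_mismatch_guard(self):
        with pytest.raises(ValueError, match="mismatch"):
            consequence_of(1, "C", "A", "ATGTAA")

    def test_codon_index_formula(self):
        cds = "ATG" + "GCT" * 299
        for pos in (1, 3, 4, 751, 900):
            c = consequence_of(pos, cds[pos - 1], "A" if cds[pos - 1] != "A" else "G",
                               cds)
            assert c.codon_index == (pos - 1) // 3 + 1


class TestAnnotatePipeline:
    def test_planted_cohort_reproduces_one_missense_many_noncoding(self, sim_clean):
        """Filtering plus annotation on a gene-dropped cohort keeps the
        planted causal missense and the linked non-coding variants, nothing
        else protein-changing."""
        res, t = sim_clean, sim_clean.truth
        policy = FilterPolicy(
            tuple(t.sequenced_case_ids),
            tuple(s for s in res.vcf_samples if s not in t.sequenced_case_ids))
        survivors = filter_recessive_private(res.variants, policy)
        annotate_consequences(survivors, res.transcript, res.coding_sequence)
        changing = protein_changing(survivors)
        assert len(changing) == 1
        v = changing[0]
        assert (v.chrom, v.pos_bp, v.ref, v.alt) \
            == (t.causal_chrom, t.causal_pos, t.causal_ref, t.causal_alt)
        assert v.consequence.hgvs_p == "p.Asp251Asn"
        linked = [s for s in survivors if s.pos_bp in set(t.linked_positions)]
        assert len(linked) == len(t.linked_positions)
        assert all(s.consequence.klass == "noncoding" for s in linked)

    def test_minus_strand_alleles_complemented(self):
        t = TranscriptModel("g", "1", "-", [(1001, 3430)], 1001, 3430)
        cds = "ATG" + "GAT" * 808 + "TAA"
        # c.751 on minus strand = genomic cds_end - 750
        g = genomic_position(751, t)
        v = VariantRecord("1", g, complement("G"), complement("A"))
        annotate_consequences([v], t, cds)
        assert v.consequence.hgvs_c == "c.751G>A"

    def test_splice_region_label(self):
        t = TranscriptModel("g", "1", "+", [(1001, 1600), (2001, 3830)],
                            1001, 3830)
        near = VariantRecord("1", 1602, "G", "A")    # 2 bp into the intron
        deep = VariantRecord("1", 1800, "G", "A")
        annotate_consequences([near, deep], t, "ATG" + "GCT" * 808 + "TAA")
        assert near.consequence.klass == "splice_region_unsupported"
        assert deep.consequence.klass == "noncoding"
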