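"""Effect classification, element intersection, overlap stats, motifs."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from snpisland.annotate import (
    Element,
    GeneModel,
    PROTEIN_CHANGING,
    ReferenceMismatchError,
    classify_effect,
    gene_set_overlap,
    intersect_elements,
    motif_scan,
    prioritize,
    read_gff3,
    write_gff3,
)
from snpisland.genome import Interval
from snpisland.islands import Island
from snpisland.pattern import Variant

BASES = "ACGT"


def single_exon_gene(chrom, start, n_codons, strand="+", gene_id="g1"):
    end = start + 3 * n_codons
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}-RA",
        chrom=chrom,
        strand=strand,
        exons=(Interval(chrom, start, end),),
        cds=(Interval(chrom, start, end),),
    )


class TestClassifyEffect:
    def test_missense_ala1357val(self):
        """A GCA->GTA change at residue 1357 is called Ala1357Val."""
        n_codons = 1400
        rng = np.random.default_rng(0)
        # codons that avoid premature stops: use a fixed non-stop codon
        seq = "GCA" * n_codons
        ref = {"2R": "NN" + seq + "NN"}
        gene = single_exon_gene("2R", 2, n_codons)
        pos = 2 + 1356 * 3 + 1  # middle base of codon 1357
        v = Variant("2R", pos, "C", "T")
        (call,) = classify_effect(v, [gene], ref)
        assert call.category == "missense"
        assert call.detail == "Ala1357Val"

    def test_one_bp_insertion_in_cds_is_frameshift(self):
        ref = {"2R": "NN" + "GCA" * 10 + "NN"}
        gene = single_exon_gene("2R", 2, 10)
        v = Variant("2R", 5, "G", "GT")
        (call,) = classify_effect(v, [gene], ref)
        assert call.category == "frameshift"

    def test_three_bp_deletion_is_inframe(self):
        ref = {"2R": "NN" + "GCA" * 10 + "NN"}
        gene = single_exon_gene("2R", 2, 10)
        v = Variant("2R", 5, "GCAG", "G")
        (call,) = classify_effect(v, [gene], ref)
        assert call.category == "inframe_indel"

    def test_third_position_synonymous(self):
        """GCT->GCC at the wobble position stays alanine (codon-table oracle)."""
        ref = {"2R": "GCT" * 10}
        gene = single_exon_gene("2R", 0, 10)
        v = Variant("2R", 2, "T", "C")
        (call,) = classify_effect(v, [gene], ref)
        assert str(Seq("GCT").translate()) == str(Seq("GCC").translate())
        assert call.category == "synonymous"
        assert call.detail == "Ala1Ala"

    def test_nonsense(self):
        ref = {"2R": "TGG" + "GCA" * 9}
        gene = single_exon_gene("2R", 0, 10)
        v = Variant("2R", 2, "G", "A")  # TGG -> TGA
        (call,) = classify_effect(v, [gene], ref)
        assert call.category == "nonsense"

    def test_minus_strand_uses_reverse_complement(self):
        """On a minus-strand gene the alt base is complemented before
        translation (cross-checked by translating the strand sequence)."""
        # genomic GCA*10; minus-strand CDS is revcomp = TGC*10 (Cys)
        ref = {"2R": "GCA" * 10}
        gene = single_exon_gene("2R", 0, 10, strand="-")
        # change genomic pos 28 (middle of last genomic codon = first CDS codon)
        v = Variant("2R", 28, "C", "T")  # CDS codon TGC -> TAC, Cys1Tyr
        (call,) = classify_effect(v, [gene], ref)
        assert call.category == "missense"
        assert call.detail == "Cys1Tyr"

    def test_splice_site_within_two_bp_of_intron_boundary(self):
        g = GeneModel(
            gene_id="g",
            transcript_id="g-RA",
            chrom="2R",
            strand="+",
            exons=(Interval("2R", 0, 30), Interval("2R", 130, 160)),
            cds=(Interval("2R", 0, 30), Interval("2R", 130, 160)),
        )
        ref = {"2R": "A" * 200}
        donor = Variant("2R", 30, "A", "T")
        deep = Variant("2R", 80, "A", "T")
        acceptor = Variant("2R", 129, "A", "T")
        assert classify_effect(donor, [g], ref)[0].category == "splice_site"
        assert classify_effect(deep, [g], ref)[0].category == "intronic"
        assert classify_effect(acceptor, [g], ref)[0].category == "splice_site"

    def test_utr_and_intergenic(self):
        g = GeneModel(
            gene_id="g",
            transcript_id="g-RA",
            chrom="2R",
            strand="+",
            exons=(Interval("2R", 10, 70),),
            cds=(Interval("2R", 20, 50),),
        )
        ref = {"2R": "A" * 200}
        assert classify_effect(Variant("2R", 12, "A", "T"), [g], ref)[0].category == "UTR"
        assert (
            classify_effect(Variant("2R", 150, "A", "T"), [g], ref)[0].category
            == "intergenic"
        )

    def test_reference_mismatch_raises(self):
        ref = {"2R": "GCA" * 10}
        gene = single_exon_gene("2R", 0, 10)
        with pytest.raises(ReferenceMismatchError):
            classify_effect(Variant("2R", 0, "T", "A"), [gene], ref)

    def test_agrees_with_translate_and_compare_oracle(self):
        """Classifier ≡ brute-force full-CDS mutation + translation on
        1,000 random SNPs over random gene models, both strands."""
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 1000:
            n_codons = int(rng.integers(5, 60))
            start = int(rng.integers(2, 50))
            strand = "+" if rng.random() < 0.5 else "-"
            length = start + 3 * n_codons + 60
            seq = "".join(rng.choice(list(BASES), size=length))
            ref = {"c": seq}
            gene = single_exon_gene("c", start, n_codons, strand=strand, gene_id="g")
            pos = int(rng.integers(start, start + 3 * n_codons))
            refbase = seq[pos]
            alt = BASES[int(rng.integers(0, 4))]
            if alt == refbase:
                continue
            v = Variant("c", pos, refbase, alt)
            (call,) = classify_effect(v, [gene], ref)

            # oracle: mutate the whole genome string, rebuild CDS, translate
            mutated = seq[:pos] + alt + seq[pos + 1 :]
            cds_ref = gene.cds_sequence(ref)
            cds_alt = gene.cds_sequence({"c": mutated})
            prot_ref = str(Seq(cds_ref).translate())
            prot_alt = str(Seq(cds_alt).translate())
            if prot_ref == prot_alt:
                expected = "synonymous"
            else:
                (diff,) = [
                    i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b
                ]
                expected = "nonsense" if prot_alt[diff] == "*" else "missense"
            assert call.category == expected, (v, strand, call)
            n_checked += 1


class TestGff3RoundTrip:
    def test_models_round_trip(self, tmp_path):
        g1 = single_exon_gene("2R", 10, 20)
        g2 = GeneModel(
            gene_id="g2",
            transcript_id="g2-RA",
            chrom="2L",
            strand="-",
            exons=(Interval("2L", 0, 40), Interval("2L", 100, 160)),
            cds=(Interval("2L", 10, 40), Interval("2L", 100, 130)),
        )
        path = write_gff3([g1, g2], tmp_path / "g.gff3")
        back = {m.transcript_id: m for m in read_gff3(path)}
        for m in (g1, g2):
            r = back[m.transcript_id]
            assert (r.chrom, r.strand, r.exons, r.cds) == (
                m.chrom,
                m.strand,
                m.exons,
                m.cds,
            )


class TestIntersectElements:
    def test_summary_counts(self):
        elems = [Element("e1", "CRE", Interval("2R", 100, 200))]
        vs = snv_list("2R", [100, 150, 199])
        hits, (nv, ne) = intersect_elements(vs, elems)
        assert (nv, ne) == (3, 1)
        assert all(h.element.element_id == "e1" for h in hits)

    def test_no_overlap(self):
        elems = [Element("e1", "CRE", Interval("2R", 100, 200))]
        hits, summary = intersect_elements(snv_list("2R", [99, 200]), elems)
        assert hits == [] and summary == (0, 0)

    def test_matches_naive_all_pairs_scan(self):
        rng = np.random.default_rng(4)
        elems = [
            Element(f"e{i}", "CRE", Interval("2R", int(s), int(s) + int(w)))
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 99_000, 300), rng.integers(50, 900, 300))
            )
        ]
        vs = snv_list("2R", rng.integers(0, 100_000, 2000))
        hits, (nv, ne) = intersect_elements(vs, elems)
        naive = {
            (v, e.element_id)
            for v in vs
            for e in elems
            if e.interval.contains(v.pos)
        }
        assert {(h.variant, h.element.element_id) for h in hits} == naive
        assert nv == len({v for v, _ in naive})
        assert ne == len({e for _, e in naive})

    def test_length_filter(self):
        elems = [
            Element("small", "CRE", Interval("2R", 0, 100)),
            Element("big", "CRE", Interval("2R", 0, 5000)),
        ]
        _, (nv, ne) = intersect_elements(
            snv_list("2R", [50]), elems, max_element_length=2000
        )
        assert (nv, ne) == (1, 1)


def snv_list(arm, positions):
    return [Variant(arm, int(p), "A", "T") for p in positions]


class TestGeneSetOverlap:
    def test_printed_rib_beaf_overlap_percent(self):
        """150 of 494 Rib-associated genes overlap the 3241 BEAF set: 30%."""
        universe = 13_000
        a = {f"g{i}" for i in range(3241)}
        b = {f"g{i}" for i in range(3091, 3091 + 494)}  # overlap of exactly 150
        overlap, percent, p = gene_set_overlap(a, b, universe)
        assert overlap == 150
        assert percent == 30
        assert 0 <= p <= 1

    def test_identical_sets(self):
        a = {f"g{i}" for i in range(40)}
        overlap, percent, p = gene_set_overlap(a, a, 100)
        assert (overlap, percent) == (40, 100)
        assert p == pytest.approx(1.0 / math.comb(100, 40), rel=1e-9)

    def test_ribosomal_protein_gene_overlap_exact_p(self):
        """61-vs-73 overlap of 53 within an 84-gene universe: percent 73 and
        the upper-tail probability from an explicit hypergeometric sum."""
        a = {f"r{i}" for i in range(61)}
        b = {f"r{i}" for i in range(8, 81)}  # |b|=73, overlap = 53
        overlap, percent, p = gene_set_overlap(a, b, 84)
        assert overlap == 53
        assert percent == 73
        exact = sum(
            math.comb(61, k) * math.comb(84 - 61, 73 - k) / math.comb(84, 73)
            for k in range(53, 62)
        )
        assert p == pytest.approx(exact, rel=1e-9)

    def test_percent_is_of_b(self):
        a = {"x", "y", "z", "w"}
        b = {"x", "y"}
        _, pct_ab, _ = gene_set_overlap(a, b, 10)
        _, pct_ba, _ = gene_set_overlap(b, a, 10)
        assert pct_ab == 100 and pct_ba == 50

    def test_empty_b_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap({"a"}, set(), 10)


class TestMotifScan:
    def test_forward_overlapping_occurrences(self):
        out = motif_scan(["CGATACGATA"], "CGATA", both_strands=False)
        assert out["total"] == 2

    def test_reverse_complement_hit(self):
        out = motif_scan(["TATCG"], "CGATA", both_strands=True)
        assert out["total"] == 1
        assert motif_scan(["TATCG"], "CGATA", both_strands=False)["total"] == 0

    def test_empty_input(self):
        out = motif_scan([], "CGATA")
        assert out["total"] == 0 and out["fraction_hit"] == 0.0

    def test_iupac_ambiguity_codes(self):
        out = motif_scan(["CGATT"], "CGATW", both_strands=False)
        assert out["total"] == 1

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            motif_scan(["ACGT"], "CGA!A")

    def test_fraction_of_sequences_hit(self):
        out = motif_scan({"a": "CGATA", "b": "TTTTT"}, "CGATA", both_strands=False)
        assert out["fraction_hit"] == 0.5


class TestPrioritize:
    @pytest.fixture
    def fixture(self):
        island = Island(Interval("2R", 10_000, 20_000), 10, 5)
        causal = Variant("2R", 15_000, "T", "G")
        coding = Variant("2R", 12_000, "G", "A")
        cre_var = Variant("2R", 13_000, "C", "A")
        outside = Variant("3L", 5_000, "A", "T")
        cands = [causal, coding, cre_var, outside]
        from snpisland.annotate import EffectCall, ElementHit

        effects = [EffectCall(coding, "t1", "missense", "Ala2Val")]
        hits = [
            ElementHit(causal, Element("PRE_1", "PRE", Interval("2R", 14_900, 15_500))),
            ElementHit(cre_var, Element("CRE_1", "CRE", Interval("2R", 12_900, 13_100))),
        ]
        return cands, effects, hits, island, causal

    def test_tier_order(self, fixture):
        cands, effects, hits, island, causal = fixture
        ranking = prioritize(cands, effects, hits, island)
        assert ranking[0][1] == causal and ranking[0][2] == 1
        assert ranking[1][2] == 2  # island protein-changing
        assert ranking[2][2] == 3  # island CRE
        assert ranking[3][2] == 4

    def test_no_pre_hits_promotes_protein_changing(self, fixture):
        cands, effects, hits, island, causal = fixture
        hits = [h for h in hits if h.element.element_class != "PRE"]
        ranking = prioritize(cands, effects, hits, island)
        assert ranking[0][2] == 2 and ranking[0][1].pos == 12_000

    def test_partition_and_order_invariance(self, fixture):
        cands, effects, hits, island, _ = fixture
        a = prioritize(cands, effects, hits, island)
        b = prioritize(list(reversed(cands)), effects, hits, island)
        assert a == b
        assert sorted(v for _, v, _, _ in a) == sorted(cands)
        assert [r for r, *_ in a] == [1, 2, 3, 4]

    def test_protein_changing_categories(self):
        assert "synonymous" not in PROTEIN_CHANGING
        assert {"missense", "frameshift", "splice_site"} <= PROTEIN_CHANGING
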