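"""Circular coordinates, strand conventions and consequence annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitovar.genome_model import (
    Consequence,
    GeneAnnotation,
    FormatError,
    MtReference,
    annotate_consequence,
    classify_variant,
    enumerate_protein_changes,
    load_reference,
    read_annotation,
    reverse_complement,
    translate_codon,
    trinucleotide_context,
    write_annotation,
)


class TestReference:
    def test_load_single_record(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chrM\nacgtacgtac\n")
        ref = load_reference(p)
        assert len(ref) == 10 and ref.sequence == "ACGTACGTAC"

    def test_load_rejects_empty_and_multi_record(self, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(FormatError):
            load_reference(empty)
        multi = tmp_path / "multi.fa"
        multi.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(FormatError):
            load_reference(multi)

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(FormatError):
            MtReference("ACGX")

    def test_position_arithmetic_wraps(self):
        ref = MtReference("ACGTA")
        assert ref.base(6) == ref.base(1) == "A"
        assert ref.fetch(4, 2) == "TAAC"  # wraps through the origin


class TestContext:
    @pytest.mark.parametrize(
        "position,strand,expected",
        [(1, "L", "AAC"), (1, "H", "GTT"), (3, "L", "CGT")],
    )
    def test_circular_context(self, position, strand, expected):
        ref = MtReference("ACGTA")
        assert trinucleotide_context(ref, position, strand) == expected

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            trinucleotide_context(MtReference("ACGTA"), 6, "L")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=40), st.data())
    def test_h_context_is_reverse_complement_of_l(self, seq, data):
        ref = MtReference(seq)
        pos = data.draw(st.integers(1, len(seq)))
        assert trinucleotide_context(ref, pos, "H") == reverse_complement(
            trinucleotide_context(ref, pos, "L")
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=30), st.data())
    def test_rotation_invariance(self, seq, data):
        """Contexts on a rotated copy are identical after coordinate shift."""
        shift = data.draw(st.integers(1, len(seq) - 1))
        pos = data.draw(st.integers(1, len(seq)))
        ref = MtReference(seq)
        rotated = MtReference(seq[shift:] + seq[:shift])
        shifted_pos = (pos - 1 - shift) % len(seq) + 1
        assert trinucleotide_context(ref, pos, "L") == trinucleotide_context(
            rotated, shifted_pos, "L"
        )


class TestConsequence:
    def test_mitochondrial_code_quirks(self):
        # TGA encodes Trp and AGA is a stop in the vertebrate mitochondrial code
        assert translate_codon("TGA") == "W"
        assert translate_codon("AGA") == "*"
        assert translate_codon("ATA") == "M"

    def test_silent_tgg_to_tga(self, toy_gene_genome):
        ref, ann = toy_gene_genome
        # codon 2 is TGG at positions 4-6; G>A at position 6 gives TGA (Trp)
        cons = classify_variant(ref, ann, 6, "G", "A")
        assert cons.category == "silent" and cons.codon_change == "TGG>TGA"

    def test_nonsense_cga_to_aga(self, toy_gene_genome):
        ref, ann = toy_gene_genome
        # codon 3 is CGA at positions 7-9; C>A at position 7 gives AGA (stop)
        cons = classify_variant(ref, ann, 7, "C", "A")
        assert cons.category == "nonsense" and cons.codon_change == "CGA>AGA"

    def test_stop_lost(self, toy_gene_genome):
        ref, ann = toy_gene_genome
        # codon 6 is TAA at positions 16-18; T>C gives CAA (Gln)
        cons = classify_variant(ref, ann, 16, "T", "C")
        assert cons.category == "stop_lost"

    def test_h_strand_gene_reads_complement(self):
        # gene on H strand: L-strand holds the reverse complement of the ORF
        orf = "ATGTGGTAA"
        ref = MtReference(reverse_complement(orf) + "ACGTAC")
        ann = [GeneAnnotation(gene="H1", start=1, end=9, feature="protein", coding_strand="H")]
        # position 9 on L is the first sense base (A of ATG); L-strand base is T
        cons = classify_variant(ref, ann, 9, "T", "C")  # sense A>G: ATG->GTG (Met->Val)
        assert cons.category == "missense"

    def test_trna_anticodon_flag(self):
        ref = MtReference("ACGT" * 10)
        ann = [
            GeneAnnotation(gene="T1", start=1, end=30, feature="tRNA", anticodon_span=(10, 12))
        ]
        inside = classify_variant(ref, ann, 11, ref.base(11), "A" if ref.base(11) != "A" else "C")
        outside = classify_variant(ref, ann, 5, ref.base(5), "A" if ref.base(5) != "A" else "C")
        assert inside.category == "tRNA" and inside.anticodon_hit
        assert outside.category == "tRNA" and not outside.anticodon_hit

    def test_indels_classified_by_frame(self, toy_gene_genome):
        ref, ann = toy_gene_genome
        fs = classify_variant(ref, ann, 5, "G", "GA")
        inframe = classify_variant(ref, ann, 5, "G", "GAAA")
        assert fs.category == "frameshift"
        assert inframe.category == "inframe_indel"

    def test_overlapping_genes_report_both(self, toy_gene_genome):
        ref, _ = toy_gene_genome
        ann = [
            GeneAnnotation(gene="A", start=1, end=18, feature="protein"),
            GeneAnnotation(gene="B", start=4, end=15, feature="protein", frame_offset=0),
        ]
        out = annotate_consequence(ref, ann, 7, "C", "A")
        assert {c.gene for c in out} == {"A", "B"}

    def test_consequence_partition_matches_brute_force(self, small_genome):
        """All 3*len single-base changes over a protein gene partition into
        silent+missense+nonsense+stop_lost, matching an independent
        enumeration via direct codon rewriting."""
        ref, ann = small_genome
        gene = next(a for a in ann if a.feature == "protein" and a.coding_strand == "L")
        counts = {"silent": 0, "missense": 0, "nonsense": 0, "stop_lost": 0}
        for _pos, _refb, _alt, cons in enumerate_protein_changes(ref, gene):
            counts[cons.category] += 1
        assert sum(counts.values()) == 3 * gene.length(len(ref))

        # oracle: rewrite the sense sequence directly, codon by codon
        sense = gene.sense_sequence(ref)
        oracle = {"silent": 0, "missense": 0, "nonsense": 0, "stop_lost": 0}
        for i in range(len(sense)):
            for alt in "ACGT":
                if alt == sense[i]:
                    continue
                ci = i // 3
                codon = sense[ci * 3 : ci * 3 + 3]
                new = codon[: i % 3] + alt + codon[i % 3 + 1 :]
                a, b = translate_codon(codon), translate_codon(new)
                if a == b:
                    oracle["silent"] += 1
                elif b == "*":
                    oracle["nonsense"] += 1
                elif a == "*":
                    oracle["stop_lost"] += 1
                else:
                    oracle["missense"] += 1
        assert counts == oracle


def test_annotation_roundtrip(tmp_path, small_genome):
    _, ann = small_genome
    p = tmp_path / "ann.tsv"
    write_annotation(ann, p)
    back = read_annotation(p)
    assert back == ann
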