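"""ORF consequences, peptide masses, breakpoint offsets, microhomology."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fusioncall.fusion_annotation import (
    FusionTranscript,
    annotation_report,
    breakpoint_offsets,
    build_fusion_transcript,
    microhomology,
    peptide_mass,
    predict_fusion_orfs,
)
from fusioncall.genome_model import GeneModel, GenomeAssembly


class TestPeptideMass:
    def test_glycine(self):
        # residue 57.0519 + water 18.0153 = 75.0672 Da
        assert peptide_mass("G") == pytest.approx(0.0750672, abs=1e-6)

    def test_diglycine(self):
        assert peptide_mass("GG") * 1000 == pytest.approx(132.1191, abs=1e-3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_unknown_letter_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            peptide_mass("GZ")

    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
    )
    def test_additive_up_to_water(self, a, b):
        combined = peptide_mass(a + b)
        assert combined == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - 18.0153 / 1000, abs=1e-9
        )


class TestOrfPrediction:
    def test_out_of_frame_readthrough_toy(self):
        # hand-translated: ATG AAA | GGC TAA -> peptide MKG, one novel residue
        ft = FusionTranscript(
            sequence="ATGAAAGGCTAA",
            junction_offset=6,
            gene5_id="g5",
            gene3_id="g3",
            gene5_cds_start=0,
        )
        orfs = predict_fusion_orfs(ft)
        assert len(orfs) == 1
        rt = orfs[0]
        assert rt.kind == "truncated_5p_readthrough"
        assert rt.peptide == "MKG"
        assert rt.novel_aa_count == 1
        assert rt.stop_offset == 9

    def test_in_frame_readthrough_flagged(self):
        # junction preserves the 3' partner frame: anchor = junction with cds3=0
        ft = FusionTranscript(
            sequence="ATGAAAGGGTAA",
            junction_offset=6,
            gene5_id="g5",
            gene3_id="g3",
            gene5_cds_start=0,
            gene3_cds_start=0,
            skipped_3p_length=0,
        )
        rt = [o for o in predict_fusion_orfs(ft) if o.kind == "truncated_5p_readthrough"][0]
        assert rt.in_frame is True and rt.peptide == "MKG"

    def test_internal_start_in_frame_with_native_stop(self):
        # internal ATG 9 nt after the junction, in frame with the downstream stop
        seq = "ATGAAACCC" + "TTTTTTTTT" + "ATGGCCTAA"
        ft = FusionTranscript(
            sequence=seq,
            junction_offset=9,
            gene5_id="g5",
            gene3_id="g3",
            gene5_cds_start=0,
            gene3_cds_start=0,
            skipped_3p_length=0,
        )
        orfs = predict_fusion_orfs(ft)
        kinds = {o.kind: o for o in orfs}
        internal = kinds["internal_start_3p"]
        assert internal.start_offset == 18
        assert internal.peptide == "MA"
        assert internal.peptide.startswith("M")

    def test_out_of_frame_atg_not_used_for_internal_start(self):
        # the only downstream ATG sits out of frame relative to the native stop
        seq = "ATGAAACCC" + "GATGCCTAAGGG"
        ft = FusionTranscript(
            sequence=seq,
            junction_offset=9,
            gene5_id="g5",
            gene3_id="g3",
            gene5_cds_start=0,
            gene3_cds_start=0,
            skipped_3p_length=0,
        )
        kinds = {o.kind for o in predict_fusion_orfs(ft)}
        assert kinds == {"truncated_5p_readthrough"}

    def test_missing_cds_start_errors(self):
        ft = FusionTranscript(
            sequence="ATGAAAGGCTAA", junction_offset=6, gene5_id="g5", gene3_id="g3"
        )
        with pytest.raises(ValueError, match="cds_start"):
            predict_fusion_orfs(ft)

    def test_predicted_peptides_have_no_internal_stop(self, mini_genome):
        genome, ann = mini_genome
        ft = build_fusion_transcript(genome, ann["gA"], 1, ann["gB"], 2)
        for orf in predict_fusion_orfs(ft):
            assert "*" not in orf.peptide
            assert orf.peptide.startswith("M")
            assert len(orf.peptide) == (orf.stop_offset - orf.start_offset) // 3


def test_build_fusion_transcript_splices_prefix_and_suffix(mini_genome):
    genome, ann = mini_genome
    from fusioncall.genome_model import spliced_sequence

    ft = build_fusion_transcript(genome, ann["gA"], 1, ann["gB"], 2)
    tx5 = spliced_sequence(genome, ann["gA"])
    tx3 = spliced_sequence(genome, ann["gB"])
    assert ft.sequence == tx5[:8] + tx3[32:]
    assert ft.junction_offset == 8
    assert ft.skipped_3p_length == 32


class TestBreakpointOffsets:
    def _gene5(self, shift=0):
        # exon 1 occupies [0,1000) -> last base index 999 (1-based position 1000)
        return GeneModel("g5", "chrA", "+", ((0 + shift, 1000 + shift), (3000 + shift, 3500 + shift)))

    def _gene3(self, shift=0):
        return GeneModel(
            "g3", "chrB", "+",
            ((0 + shift, 200 + shift), (1000 + shift, 1200 + shift), (6000 + shift, 6400 + shift)),
        )

    def test_printed_geometry_mirrored_on_toy_coordinates(self):
        """679 bp past exon 1 of the 5' gene; 3931 bp upstream of exon 3 of the 3' gene."""
        g5, g3 = self._gene5(), self._gene3()
        bp5 = ("chrA", 999 + 679)
        bp3 = ("chrB", 6000 - 3931)
        off = breakpoint_offsets(bp5, bp3, g5, g3, last_exon5=1, first_exon3=3)
        assert off.dist_to_5p_exon_end == 679
        assert off.dist_to_3p_exon_start == 3931

    def test_breakpoint_at_exon_boundary_gives_zero(self):
        g5, g3 = self._gene5(), self._gene3()
        off = breakpoint_offsets(("chrA", 999), ("chrB", 6000), g5, g3, 1, 3)
        assert off.dist_to_5p_exon_end == 0
        assert off.dist_to_3p_exon_start == 0

    def test_breakpoint_inside_exon_errors(self):
        g5, g3 = self._gene5(), self._gene3()
        with pytest.raises(ValueError, match="inside"):
            breakpoint_offsets(("chrA", 500), ("chrB", 2000), g5, g3, 1, 3)

    def test_invariant_under_coordinate_translation(self):
        off_a = breakpoint_offsets(
            ("chrA", 999 + 679), ("chrB", 6000 - 3931), self._gene5(), self._gene3(), 1, 3
        )
        off_b = breakpoint_offsets(
            ("chrA", 10_999 + 679),
            ("chrB", 16_000 - 3931),
            self._gene5(shift=10_000),
            self._gene3(shift=10_000),
            1,
            3,
        )
        assert off_a.dist_to_5p_exon_end == off_b.dist_to_5p_exon_end
        assert off_a.dist_to_3p_exon_start == off_b.dist_to_3p_exon_start

    def test_minus_strand_mirror(self):
        # mirror the plus-strand 5' gene across position 4000
        L = 4000
        g5m = GeneModel("g5m", "chrA", "-", ((L - 3500, L - 3000), (L - 1000, L)))
        # exon 1 (tx order) is the rightmost exon; its last tx base is genomic L-1000
        bp = ("chrA", L - 1000 - 679)
        off = breakpoint_offsets(bp, ("chrB", 6000), g5m, self._gene3(), 1, 3)
        assert off.dist_to_5p_exon_end == 679


class TestMicrohomology:
    def test_identical_flanks(self):
        ctx = "TTTTTTTTTTGCGCGCGCGC" + "AAAAAAAAAAAAAAAAAAAA"
        m = microhomology(ctx, 20, ctx, 20, max_probe=10)
        assert m.length == 10

    def test_no_homology(self):
        a = "A" * 15 + "G" * 15
        b = "C" * 15 + "T" * 15
        m = microhomology(a, 15, b, 15, max_probe=10)
        assert m.length == 0 and m.side == "none"

    def test_engineered_four_nt_duplicated_flank(self):
        # both partners carry TCGA immediately 5' of their junction point
        a = "A" * 11 + "TCGA" + "GGGGGGGGGGGGGGG"
        b = "C" * 11 + "TCGA" + "TTTTTTTTTTTTTTT"
        m = microhomology(a, 15, b, 15, max_probe=15)
        assert m.length == 4 and m.side == "5p"

    def test_symmetry(self):
        a = "A" * 11 + "TCGA" + "GGTTGGTTGGTTGGT"
        b = "C" * 11 + "TCGA" + "GGTTCCCCCCCCCCC"
        m1 = microhomology(a, 15, b, 15, max_probe=15)
        m2 = microhomology(b, 15, a, 15, max_probe=15)
        assert (m1.length, m1.side) == (m2.length, m2.side)

    def test_short_context_errors(self):
        with pytest.raises(ValueError, match="context"):
            microhomology("ACGT", 2, "ACGTACGTACGTACGTACGTACGTACGTACGT", 16)


def test_annotation_report_rounds_masses():
    ft = FusionTranscript(
        sequence="ATGAAAGGCTAA", junction_offset=6, gene5_id="g5", gene3_id="g3",
        gene5_cds_start=0,
    )
    report = annotation_report(predict_fusion_orfs(ft))
    orf = report["orfs"][0]
    assert orf["mass_kda_rounded"] == 0  # MKG is tiny
    assert orf["peptide_length"] == 3
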