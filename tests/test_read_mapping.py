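"""QC trimming, mapper-vs-oracle equivalence, pair classification, remap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fusioncall.genome_model import Annotation, GeneModel, revcomp
from fusioncall.read_mapping import (
    AlignmentRecord,
    BruteForceMapper,
    PairClass,
    Read,
    ReferenceIndex,
    classify_pair,
    map_read,
    qc_reads,
    read_sam,
    remap_validate,
    write_sam,
)


def _read(bases, quals=None, rid="r1", mate=1):
    return Read(rid, mate, bases, quals if quals is not None else [35] * len(bases))


class TestQc:
    def test_high_quality_read_unchanged(self):
        reads, stats = qc_reads([_read("A" * 75)])
        assert len(reads[0]) == 75 and stats.trimmed == 0

    def test_trim_below_min_length_removes_read(self):
        quals = [35] * 75
        quals[40] = 10
        reads, stats = qc_reads([_read("A" * 75, quals)])
        assert reads == [] and stats.removed == 1

    def test_trim_retains_long_enough_read(self):
        quals = [35] * 100
        quals[60] = 10
        reads, _ = qc_reads([_read("A" * 100, quals)])
        assert len(reads) == 1 and len(reads[0]) == 60

    @given(st.lists(st.integers(2, 41), min_size=45, max_size=100))
    def test_idempotent(self, quals):
        bases = "A" * len(quals)
        once, _ = qc_reads([_read(bases, quals)])
        twice, _ = qc_reads(once)
        assert [(r.bases, r.qualities) for r in once] == [
            (r.bases, r.qualities) for r in twice
        ]


def _random_refs(rng, sizes):
    return {
        f"ref{i}": "".join(np.take(list("ACGT"), rng.integers(0, 4, n)))
        for i, n in enumerate(sizes)
    }


class TestMapper:
    def test_exact_substring_single_unique_hit(self):
        refs = _random_refs(np.random.default_rng(0), [500])
        index = ReferenceIndex(refs)
        read = _read(refs["ref0"][100:160])
        hits = map_read(index, read, 2)
        assert len(hits) == 1
        assert (hits[0].reference, hits[0].position, hits[0].strand) == ("ref0", 100, "+")
        assert hits[0].mismatch_count == 0 and hits[0].is_unique

    def test_repeated_locus_reports_tied_hits_not_unique(self):
        core = "".join(np.take(list("ACGT"), np.random.default_rng(1).integers(0, 4, 60)))
        refs = {"ref0": "AAAA" + core + "CCCC" + core + "GGGG"}
        index = ReferenceIndex(refs)
        hits = map_read(index, _read(core), 0)
        assert len(hits) == 2 and not any(h.is_unique for h in hits)

    def test_read_shorter_than_seed_is_unmapped(self):
        refs = {"ref0": "ACGT" * 50}
        index = ReferenceIndex(refs, seed_length=16)
        assert map_read(index, _read("ACGTACGT"), 2) == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        refs = _random_refs(rng, [800])
        index = ReferenceIndex(refs)
        fwd = refs["ref0"][200:275]
        hits_f = map_read(index, _read(fwd), 1)
        hits_r = map_read(index, _read(revcomp(fwd)), 1)
        assert [(h.reference, h.position, h.mismatch_count) for h in hits_f] == [
            (h.reference, h.position, h.mismatch_count) for h in hits_r
        ]
        assert {h.strand for h in hits_f} == {"+"} and {h.strand for h in hits_r} == {"-"}

    @pytest.mark.parametrize("read_len", [40, 75])  # 40 exercises the brute-force fallback
    def test_matches_bruteforce_oracle(self, read_len):
        rng = np.random.default_rng(3)
        refs = _random_refs(rng, [3000, 1500])
        index = ReferenceIndex(refs)
        oracle = BruteForceMapper(refs)
        reads = []
        for i in range(120):
            name = "ref0" if i % 2 == 0 else "ref1"
            start = int(rng.integers(0, len(refs[name]) - read_len))
            seq = list(refs[name][start : start + read_len])
            for pos in rng.choice(read_len, size=int(rng.integers(0, 4)), replace=False):
                seq[pos] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5:
                seq = list(revcomp("".join(seq)))
            reads.append("".join(seq))
        for mm in (0, 1, 2):
            for seq in reads:
                all_hits = oracle.map(seq, mm)
                expected = []
                if all_hits:
                    best = min(h[3] for h in all_hits)
                    expected = sorted(h for h in all_hits if h[3] == best)
                got = map_read(index, _read(seq), mm)
                assert [(h.reference, h.position, h.strand, h.mismatch_count) for h in got] == expected


@pytest.fixture
def three_gene_annotation():
    return Annotation(
        [
            GeneModel("gA", "chr19", "+", ((100, 400),)),
            GeneModel("gB", "chr13", "+", ((100, 400),)),
            GeneModel("gC", "chr19", "+", ((300, 700),)),  # overlaps gA
            GeneModel("gD", "chr19", "+", ((5000, 5400),)),
        ]
    )


def _aln(ref, pos, mm=0, mate=1, length=75):
    return AlignmentRecord(f"r", mate, ref, pos, "+", mm, length)


class TestClassifyPair:
    def test_two_genes_different_chromosomes_inconsistent(self, three_gene_annotation):
        cls, a, b = classify_pair(_aln("gA", 10), _aln("gB", 10, mate=2), three_gene_annotation)
        assert cls is PairClass.INCONSISTENT_TWO_GENES and {a, b} == {"gA", "gB"}

    def test_overlapping_genes_discarded(self, three_gene_annotation):
        cls, *_ = classify_pair(_aln("gA", 10), _aln("gC", 10, mate=2), three_gene_annotation)
        assert cls is PairClass.DISCARDED_OVERLAPPING

    def test_one_end_mapped(self, three_gene_annotation):
        cls, a, b = classify_pair(_aln("gA", 10), None, three_gene_annotation)
        assert cls is PairClass.ONE_END_MAPPED and a == "gA" and b is None

    def test_unmapped(self, three_gene_annotation):
        assert classify_pair(None, None, three_gene_annotation)[0] is PairClass.UNMAPPED

    def test_same_gene_consistent(self, three_gene_annotation):
        cls, *_ = classify_pair(_aln("gD", 1), _aln("gD", 40, mate=2), three_gene_annotation)
        assert cls is PairClass.CONSISTENT_SAME_GENE

    def test_mismatch_above_tier_tolerance_blocks_chimera(self, three_gene_annotation):
        cls, *_ = classify_pair(
            _aln("gA", 10), _aln("gB", 10, mm=1, mate=2), three_gene_annotation, 0
        )
        assert cls is not PairClass.INCONSISTENT_TWO_GENES

    def test_genomic_tier_resolution_via_interval_index(self, three_gene_annotation):
        # placement on chr19 inside gD only
        cls, a, b = classify_pair(
            _aln("chr19", 5100), _aln("gB", 5, mate=2), three_gene_annotation, 2
        )
        assert cls is PairClass.INCONSISTENT_TWO_GENES and a == "gD"


class TestRemapValidate:
    def test_unique_read_passes(self):
        rng = np.random.default_rng(4)
        refs = _random_refs(rng, [1000])
        seq = refs["ref0"][100:150]
        current = AlignmentRecord("r", 1, "ref0", 100, "+", 0, 50)
        assert remap_validate(seq, refs, current)

    def test_verbatim_copy_in_decoy_fails(self):
        rng = np.random.default_rng(5)
        refs = _random_refs(rng, [1000])
        seq = refs["ref0"][100:150]
        refs["decoy"] = "TTTT" + seq + "AAAA"  # identical 50-mer planted elsewhere
        current = AlignmentRecord("r", 1, "ref0", 100, "+", 0, 50)
        assert not remap_validate(seq, refs, current)

    def test_better_alternative_fails(self):
        rng = np.random.default_rng(6)
        refs = _random_refs(rng, [600])
        read = refs["ref0"][300:350]  # 0 mismatches at the claimed locus
        # an alternative locus carrying the read with a single substitution
        variant = "T" + read[1:] if read[0] != "T" else "G" + read[1:]
        refs["alt"] = "AACC" + variant + "GGTT"
        # claimed placement with an inflated mismatch count of 2: the 1-mm
        # rival scores better, so validation must fail
        current = AlignmentRecord("r", 1, "ref0", 10, "+", 2, 50)
        assert not remap_validate(read, refs, current)

    def test_same_locus_exclusion(self):
        rng = np.random.default_rng(7)
        refs = _random_refs(rng, [1000])
        seq = refs["ref0"][100:150]
        refs["transcript"] = seq  # the gene's own spliced copy
        current = AlignmentRecord("r", 1, "transcript", 0, "+", 0, 50)
        assert not remap_validate(seq, refs, current)
        assert remap_validate(
            seq, refs, current, same_locus=lambda name, pos, strand: name == "ref0"
        )


class TestSamInterchange:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        refs = _random_refs(rng, [400])
        read = _read(refs["ref0"][30:90], rid="q1")
        rec = AlignmentRecord("q1", 1, "ref0", 30, "+", 0, 60)
        path = tmp_path / "out.sam"
        write_sam([(read, rec)], {"ref0": 400}, path)
        loaded = read_sam(path)
        assert len(loaded) == 1
        got = loaded[0]
        assert (got.read_id, got.reference, got.position, got.strand, got.mismatch_count) == (
            "q1",
            "ref0",
            30,
            "+",
            0,
        )

    def test_missing_nm_tag_rejected(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref0\tLN:100\n"
            "q1\t0\tref0\t11\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        with pytest.raises(ValueError, match="NM"):
            read_sam(path)
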