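"""Read QC and a minimal exact-seed, Hamming-extension mapper.

The mapper replaces the external aligners of a classic two-tier
(transcriptome-then-genome) fusion discovery workflow while keeping their
contracts: it reports *all* tied-best ungapped placements of a read on
either strand with at most ``max_mismatches`` substitutions, and is
exactly equivalent to a brute-force Hamming scan. Equivalence is
guaranteed by pigeonhole seeding: a read is seeded from
``max_mismatches + 1`` disjoint segments (at least one of which must be
error-free in any qualifying placement); reads too short to carry that
many seed segments fall back to the brute-force scan.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import Annotation, revcomp


@dataclass
class Read:
    """One sequencing read with phred quality scores."""

    id: str
    mate: int  # 1 or 2
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.id}: bases/qualities length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """One ungapped placement of a read on a reference sequence."""

    read_id: str
    mate: int
    reference: str
    position: int  # 0-based start on the reference forward strand
    strand: str  # '+' read matches forward, '-' its reverse complement does
    mismatch_count: int
    length: int
    is_unique: bool = True


class PairClass(enum.Enum):
    """Joint classification of a mate pair after gene assignment."""

    CONSISTENT_SAME_GENE = "consistent_same_gene"
    INCONSISTENT_TWO_GENES = "inconsistent_two_genes"
    ONE_END_MAPPED = "one_end_mapped"
    UNMAPPED = "unmapped"
    DISCARDED_OVERLAPPING = "discarded_overlapping"


@dataclass
class QCStats:
    input: int = 0
    trimmed: int = 0
    removed: int = 0
    kept: int = 0


def read_fastq(path: str | Path, mate: int) -> list[Read]:
    """Load a phred+33 FASTQ file into Read objects."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, mate, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        )
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def qc_reads(
    reads: Iterable[Read], min_quality: int = 15, min_length: int = 45
) -> tuple[list[Read], QCStats]:
    """Quality-trim reads 5'->3' and drop the ones left too short.

    Each read is truncated at the first base (scanning 5' to 3') whose
    quality falls below ``min_quality``; reads shorter than
    ``min_length`` after trimming are removed. Idempotent.
    """
    stats = QCStats()
    kept: list[Read] = []
    for read in reads:
        stats.input += 1
        cut = len(read)
        for i, q in enumerate(read.qualities):
            if q < min_quality:
                cut = i
                break
        if cut < len(read):
            stats.trimmed += 1
            read = Read(read.id, read.mate, read.bases[:cut], read.qualities[:cut])
        if len(read) < min_length:
            stats.removed += 1
            continue
        stats.kept += 1
        kept.append(read)
    return kept, stats


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_mismatches(ref_arr: np.ndarray, q_arr: np.ndarray) -> np.ndarray:
    """Hamming mismatch count of the query at every offset of one reference."""
    if len(ref_arr) < len(q_arr):
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(ref_arr, len(q_arr))
    return (windows != q_arr).sum(axis=1)


class BruteForceMapper:
    """Exhaustive Hamming scan over a reference set; the mapper's oracle."""

    def __init__(self, references: Mapping[str, str]):
        self.references = dict(references)
        self._encoded = {name: _encode(seq.upper()) for name, seq in references.items()}

    def map(self, seq: str, max_mismatches: int) -> list[tuple[str, int, str, int]]:
        """All placements (reference, position, strand, mismatches) within tolerance."""
        out: list[tuple[str, int, str, int]] = []
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            q_arr = _encode(q.upper())
            for name in sorted(self._encoded):
                mm = _scan_mismatches(self._encoded[name], q_arr)
                for pos in np.nonzero(mm <= max_mismatches)[0]:
                    out.append((name, int(pos), strand, int(mm[pos])))
        out.sort()
        return out


class ReferenceIndex:
    """Seed k-mer index over a reference set for the seed-and-extend mapper."""

    def __init__(self, references: Mapping[str, str], seed_length: int = 16):
        if seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        self.seed_length = seed_length
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._encoded = {name: _encode(seq) for name, seq in self.references.items()}
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.references):
            seq = self.references[name]
            for i in range(len(seq) - seed_length + 1):
                self._kmers.setdefault(seq[i : i + seed_length], []).append((name, i))
        self._brute = None

    def _brute_mapper(self) -> BruteForceMapper:
        if self._brute is None:
            self._brute = BruteForceMapper(self.references)
        return self._brute

    def _candidates(self, q: str, max_mismatches: int) -> set[tuple[str, int]] | None:
        """Candidate (reference, position) placements via pigeonhole seeding.

        Returns None when the read cannot carry max_mismatches+1 disjoint
        seed segments, signalling the brute-force fallback.
        """
        k = self.seed_length
        n_seg = max_mismatches + 1
        seg = len(q) // n_seg
        if seg < k:
            return None
        cands: set[tuple[str, int]] = set()
        for i in range(n_seg):
            off = i * seg
            for name, pos in self._kmers.get(q[off : off + k], ()):
                start = pos - off
                if 0 <= start and start + len(q) <= len(self.references[name]):
                    cands.add((name, start))
        return cands

    def placements(self, seq: str, max_mismatches: int) -> list[tuple[str, int, str, int]]:
        """All placements of a sequence within the mismatch tolerance."""
        seq = seq.upper()
        if len(seq) < self.seed_length:
            return []
        out: list[tuple[str, int, str, int]] = []
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            cands = self._candidates(q, max_mismatches)
            if cands is None:
                for name, pos, s, mm in self._brute_mapper().map(seq, max_mismatches):
                    if s == strand:
                        out.append((name, pos, strand, mm))
                continue
            q_arr = _encode(q)
            for name, start in cands:
                window = self._encoded[name][start : start + len(q)]
                mm = int((window != q_arr).sum())
                if mm <= max_mismatches:
                    out.append((name, start, strand, mm))
        out.sort()
        return out


def map_read(
    index: ReferenceIndex, read: Read, max_mismatches: int = 2
) -> list[AlignmentRecord]:
    """Map one read, returning all tied-best placements.

    Placements are reported in (reference, position, strand) order;
    ``is_unique`` is set when exactly one best placement exists. Reads
    shorter than the seed length are unmapped (empty list).
    """
    placements = index.placements(read.bases, max_mismatches)
    if not placements:
        return []
    best = min(p[3] for p in placements)
    tied = [p for p in placements if p[3] == best]
    unique = len(tied) == 1
    return [
        AlignmentRecord(
            read_id=read.id,
            mate=read.mate,
            reference=name,
            position=pos,
            strand=strand,
            mismatch_count=mm,
            length=len(read),
            is_unique=unique,
        )
        for name, pos, strand, mm in tied
    ]


def resolve_genes(aln: AlignmentRecord | None, annotation: Annotation) -> list[str]:
    """Gene ids an alignment falls in: the reference itself (transcriptome
    tier) or all genes its genomic interval overlaps (genome tier)."""
    if aln is None:
        return []
    if aln.reference in annotation:
        return [aln.reference]
    return [
        g.gene_id
        for g in annotation.overlapping(aln.reference, aln.position, aln.position + aln.length)
    ]


def classify_pair(
    aln1: AlignmentRecord | None,
    aln2: AlignmentRecord | None,
    annotation: Annotation,
    max_mismatches_chimera: int = 0,
) -> tuple[PairClass, str | None, str | None]:
    """Classify a mate pair by the genes its alignments resolve to.

    Both mates in one gene -> consistent; in two distinct non-overlapping
    genes within the tier's chimera mismatch tolerance -> inconsistent
    (fusion evidence); in overlapping genes (or an ambiguous multi-gene
    placement) -> discarded; otherwise one-end-mapped or unmapped.
    Returns the class together with the resolved gene ids.
    """
    g1 = resolve_genes(aln1, annotation)
    g2 = resolve_genes(aln2, annotation)
    if not g1 and not g2:
        return PairClass.UNMAPPED, None, None
    if not g1 or not g2:
        only = (g1 or g2)
        gene = only[0] if len(only) == 1 else None
        if gene is None:
            return PairClass.DISCARDED_OVERLAPPING, None, None
        return (PairClass.ONE_END_MAPPED, gene, None) if g1 else (
            PairClass.ONE_END_MAPPED,
            None,
            gene,
        )
    if len(g1) > 1 or len(g2) > 1:
        return PairClass.DISCARDED_OVERLAPPING, None, None
    a, b = g1[0], g2[0]
    if a == b:
        return PairClass.CONSISTENT_SAME_GENE, a, b
    ga, gb = annotation[a], annotation[b]
    if ga.chrom == gb.chrom and ga.start < gb.end and gb.start < ga.end:
        return PairClass.DISCARDED_OVERLAPPING, a, b
    assert aln1 is not None and aln2 is not None
    if (
        aln1.mismatch_count <= max_mismatches_chimera
        and aln2.mismatch_count <= max_mismatches_chimera
    ):
        return PairClass.INCONSISTENT_TWO_GENES, a, b
    # a mate above the tier's chimera tolerance is not confidently placed
    return PairClass.ONE_END_MAPPED, a, b


def remap_validate(
    read_seq: str,
    references: Mapping[str, str] | BruteForceMapper,
    current: AlignmentRecord,
    same_locus=None,
) -> bool:
    """Check that a fusion-supporting placement has no equal-or-better rival.

    Exhaustively rescans the full reference set (its own oracle) and
    returns False when any alternative placement reaches a mismatch count
    <= the current one. ``same_locus(reference, position, strand)`` may
    mark placements that are the *same* locus as the current one (e.g. a
    transcript's own genomic copy) so they are not counted as rivals.
    """
    mapper = (
        references
        if isinstance(references, BruteForceMapper)
        else BruteForceMapper(references)
    )
    for name, pos, strand, mm in mapper.map(read_seq, current.mismatch_count):
        if (name, pos, strand) == (current.reference, current.position, current.strand):
            continue
        if same_locus is not None and same_locus(name, pos, strand):
            continue
        return False
    return True


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Ingest external alignments from SAM; the NM tag is mandatory."""
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if not aln.has_tag("NM"):
                raise ValueError(f"{aln.query_name}: SAM record lacks NM tag")
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    mate=2 if aln.is_read2 else 1,
                    reference=aln.reference_name,
                    position=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    mismatch_count=int(aln.get_tag("NM")),
                    length=aln.query_length,
                    is_unique=not aln.is_secondary,
                )
            )
    return records


def write_sam(
    alignments: Sequence[tuple[Read, AlignmentRecord]],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignments as minimal SAM (ungapped M CIGAR, NM tag)."""
    import pysam

    names = sorted(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, rec in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            seq = read.bases if rec.strand == "+" else revcomp(read.bases)
            quals = read.qualities if rec.strand == "+" else read.qualities[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.flag = (16 if rec.strand == "-" else 0) | (128 if rec.mate == 2 else 64) | 1
            a.reference_id = names.index(rec.reference)
            a.reference_start = rec.position
            a.mapping_quality = 60 if rec.is_unique else 0
            a.cigartuples = [(0, rec.length)]
            a.set_tag("NM", rec.mismatch_count)
            out.write(a)
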