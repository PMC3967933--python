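"""Reference data model: assemblies, gene structures, interval queries.

Coordinates are 0-based half-open throughout the package; user-facing
reports convert to 1-based inclusive (genome-browser convention) at the
formatting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

Strand = Literal["+", "-"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def format_position(chrom: str, pos0: int) -> str:
    """Render an internal 0-based position as a 1-based browser-style locus."""
    return f"{chrom}:{pos0 + 1:,}"


class AnnotationParseError(ValueError):
    """Malformed annotation line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class GenomeAssembly:
    """A set of named chromosome sequences (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("assembly has no chromosomes")
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            clean[name] = seq.upper()
        self.sequences = clean

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the half-open interval [start, end) on chrom."""
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured gene on one chromosome.

    ``exons`` are genomic-order half-open intervals; ``cds_start`` is a
    transcript-relative (transcription-order) offset of the start codon,
    when known.
    """

    gene_id: str
    chrom: str
    strand: Strand
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.gene_id}: invalid exon interval ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e
        if self.cds_start is not None and not (
            0 <= self.cds_start < self.transcript_length
        ):
            raise ValueError(f"{self.gene_id}: cds_start outside transcript")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (exon 1 first)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def intron_tx(self, index: int) -> tuple[int, int]:
        """Genomic interval of the intron after transcription-order exon ``index`` (1-based)."""
        if not (1 <= index <= self.n_exons - 1):
            raise ValueError(
                f"{self.gene_id}: intron index {index} out of range (1..{self.n_exons - 1})"
            )
        if self.strand == "+":
            return (self.exons[index - 1][1], self.exons[index][0])
        # minus strand: intron k in transcription order lies genomically
        # between exons (n-k) and (n-k+1) counted from the left
        n = self.n_exons
        return (self.exons[n - index - 1][1], self.exons[n - index][0])

    def genomic_to_transcript(self, gpos: int) -> int:
        """Transcript-relative offset of a genomic position inside an exon."""
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= gpos < e:
                    return off + (gpos - s)
                off += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= gpos < e:
                    return off + (e - 1 - gpos)
                off += e - s
        raise ValueError(f"{self.gene_id}: position {gpos} not exonic")

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic position of a transcript-relative (transcription-order) offset."""
        if not (0 <= tpos < self.transcript_length):
            raise ValueError(f"{self.gene_id}: transcript offset {tpos} out of range")
        off = tpos
        for s, e in self.exons_tx_order():
            if off < e - s:
                return s + off if self.strand == "+" else e - 1 - off
            off -= e - s
        raise AssertionError("unreachable")


class Annotation:
    """A collection of GeneModels with a per-chromosome interval index."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            self.genes[gene.gene_id] = gene
            self._trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, gene.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose genomic span intersects [start, end), sorted by id."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[g] for g in hits]

    def to_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in self.genes.values():
                sizes = ",".join(str(e - s) for s, e in gene.exons) + ","
                starts = ",".join(str(s - gene.start) for s, e in gene.exons) + ","
                if gene.cds_start is None:
                    thick_start = thick_end = gene.start
                else:
                    anchor = gene.transcript_to_genomic(gene.cds_start)
                    if gene.strand == "+":
                        thick_start, thick_end = anchor, gene.end
                    else:
                        thick_start, thick_end = gene.start, anchor + 1
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            str(gene.start),
                            str(gene.end),
                            gene.gene_id,
                            "0",
                            gene.strand,
                            str(thick_start),
                            str(thick_end),
                            "0",
                            str(gene.n_exons),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )


def _bed12_gene(fields: list[str], lineno: int) -> GeneModel:
    if len(fields) < 12:
        raise AnnotationParseError(
            f"expected 12 BED12 columns, got {len(fields)}", lineno
        )
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start = int(fields[6])
        thick_end = int(fields[7])
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationParseError(f"unparseable field: {exc}", lineno) from None
    if strand not in ("+", "-"):
        raise AnnotationParseError(f"invalid strand {strand!r}", lineno)
    if len(sizes) != block_count or len(offsets) != block_count:
        raise AnnotationParseError("blockCount does not match block lists", lineno)
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    if exons and exons[-1][1] != end:
        raise AnnotationParseError("blocks do not span chromEnd", lineno)
    try:
        gene = GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)
    except ValueError as exc:
        raise AnnotationParseError(str(exc), lineno) from None
    if thick_start < thick_end:
        # derive transcript-relative CDS start from thickStart/thickEnd
        gpos = thick_start if strand == "+" else thick_end - 1
        try:
            cds = gene.genomic_to_transcript(gpos)
        except ValueError:
            raise AnnotationParseError("thickStart not exonic", lineno) from None
        gene = GeneModel(
            gene_id=name, chrom=chrom, strand=strand, exons=exons, cds_start=cds
        )
    return gene


def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise AnnotationParseError(f"malformed attribute {part!r}", lineno)
        key, value = part.split(" ", 1)
        out[key] = value.strip().strip('"')
    return out


def load_annotation(path: str | Path, dialect: str = "bed12") -> Annotation:
    """Load gene models from a BED12 or minimal-GTF file.

    The minimal GTF dialect keeps one transcript per gene: every ``exon``
    feature is grouped by its ``gene_id`` attribute. 1-based GTF and
    0-based BED coordinates are both normalized to the internal 0-based
    half-open convention.
    """
    dialect = dialect.lower()
    if dialect not in ("bed12", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    if dialect == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_bed12_gene(line.split("\t"), lineno))
    else:
        grouped: dict[str, dict] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise AnnotationParseError(
                        f"expected 9 GTF columns, got {len(fields)}", lineno
                    )
                if fields[2] != "exon":
                    continue
                try:
                    start = int(fields[3]) - 1  # GTF is 1-based inclusive
                    end = int(fields[4])
                except ValueError:
                    raise AnnotationParseError("unparseable coordinates", lineno) from None
                strand = fields[6]
                if strand not in ("+", "-"):
                    raise AnnotationParseError(f"invalid strand {strand!r}", lineno)
                attrs = _parse_gtf_attributes(fields[8], lineno)
                if "gene_id" not in attrs:
                    raise AnnotationParseError("exon without gene_id attribute", lineno)
                gid = attrs["gene_id"]
                entry = grouped.setdefault(
                    gid, {"chrom": fields[0], "strand": strand, "exons": [], "line": lineno}
                )
                if entry["chrom"] != fields[0] or entry["strand"] != strand:
                    raise AnnotationParseError(
                        f"gene {gid!r} spans chromosomes/strands", lineno
                    )
                entry["exons"].append((start, end))
        for gid, entry in grouped.items():
            exons = tuple(sorted(entry["exons"]))
            try:
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        chrom=entry["chrom"],
                        strand=entry["strand"],
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise AnnotationParseError(str(exc), entry["line"]) from None
    try:
        return Annotation(genes)
    except ValueError as exc:
        raise AnnotationParseError(str(exc)) from None


def spliced_sequence(genome: GenomeAssembly, gene: GeneModel) -> str:
    """Mature (spliced) transcript sequence of a gene, in sense orientation."""
    if gene.chrom not in genome:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in assembly")
    parts = [genome.fetch(gene.chrom, s, e) for s, e in gene.exons]
    seq = "".join(parts)
    return seq if gene.strand == "+" else revcomp(seq)


PairKind = Literal[
    "overlapping", "neighbor_readthrough", "long_intrachromosomal", "interchromosomal"
]


@dataclass(frozen=True)
class GenePairRelation:
    """Genomic relationship of a gene pair; gap is defined on-chromosome only."""

    kind: PairKind
    gap: int | None = None


def classify_gene_pair(
    a: GeneModel, b: GeneModel, neighbor_max_gap: int = 100_000
) -> GenePairRelation:
    """Classify a gene pair by genomic geometry.

    Different chromosomes -> interchromosomal; intersecting spans ->
    overlapping; same-chromosome gap <= neighbor_max_gap ->
    neighbor_readthrough (read-through chimera territory); otherwise
    long_intrachromosomal. Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return GenePairRelation("interchromosomal", None)
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    if lo.end > hi.start:
        return GenePairRelation("overlapping", 0)
    gap = hi.start - lo.end
    if gap <= neighbor_max_gap:
        return GenePairRelation("neighbor_readthrough", gap)
    return GenePairRelation("long_intrachromosomal", gap)


def _kmer_set(seq: str, k: int) -> set[str]:
    # k-mers containing N carry no homology information and are excluded
    return {
        seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]
    }


def shared_kmer_fraction(a_seq: str, b_seq: str, k: int = 31) -> float:
    """Fraction of shared k-mers, normalized by the smaller k-mer set.

    Used as the operational criterion for the "homologous genes with
    shared sequences" exclusion; symmetric in its arguments.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(a_seq) < k or len(b_seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    ka = _kmer_set(a_seq.upper(), k)
    kb = _kmer_set(b_seq.upper(), k)
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 0.0
    return len(ka & kb) / denom
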