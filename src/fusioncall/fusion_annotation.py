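"""Translational consequences, breakpoint offsets, and microhomology.

A splicing-mediated fusion transcript typically admits two products: a
readthrough ORF translated from the 5' partner's native start codon that
runs out of frame across the junction to a premature stop (a truncated
5' protein plus a short tail of novel residues), and an internal-start
isoform translated from the first downstream ATG that is in frame with
the 3' partner's native stop codon (an N-terminally truncated 3'
protein). Masses use average amino-acid residue masses; report-layer
rounding to integer kDa matches the granularity such products are
usually quoted at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .genome_model import GeneModel, GenomeAssembly, spliced_sequence

# average (not monoisotopic) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}
WATER_MASS = 18.0153

_CODON_STOP = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class FusionTranscript:
    """A fusion transcript with partner gene context.

    ``gene5_cds_start`` is the 5' partner's start-codon offset, which is
    also its offset in the fusion (the retained 5' exons are a transcript
    prefix). ``gene3_cds_start`` refers to the 3' partner's *native*
    transcript; ``skipped_3p_length`` is the total length of the 3'
    partner's exons lost to the fusion, so native transcript position
    ``x`` maps to fusion position ``junction_offset + x - skipped_3p_length``.
    """

    sequence: str
    junction_offset: int
    gene5_id: str
    gene3_id: str
    gene5_cds_start: int | None = None
    gene3_cds_start: int | None = None
    skipped_3p_length: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)):
            raise ValueError("junction_offset must fall strictly inside the transcript")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class OrfPrediction:
    kind: Literal["truncated_5p_readthrough", "internal_start_3p"]
    start_offset: int  # nt offset of the start codon in the fusion transcript
    stop_offset: int  # nt offset of the stop codon
    peptide: str
    mass_kda: float
    novel_aa_count: int | None = None  # readthrough kind only
    in_frame: bool | None = None  # readthrough: junction preserves 3' partner frame


@dataclass(frozen=True)
class BreakpointOffsets:
    breakpoint5: tuple[str, int]
    breakpoint3: tuple[str, int]
    dist_to_5p_exon_end: int
    dist_to_3p_exon_start: int


@dataclass(frozen=True)
class MicrohomologyResult:
    length: int
    side: Literal["5p", "3p", "none"]


def peptide_mass(peptide: str) -> float:
    """Average molecular mass of a peptide chain, in kDa."""
    if not peptide:
        raise ValueError("empty peptide")
    total = WATER_MASS
    for aa in peptide:
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid {aa!r}") from None
    return total / 1000.0


def _translate_to_stop(seq: str, start: int) -> tuple[str, int]:
    """Translate from ``start`` to the first in-frame stop codon.

    Returns (peptide, stop codon offset); raises when the frame runs off
    the end without a stop.
    """
    peptide = []
    pos = start
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in _CODON_STOP:
            return "".join(peptide), pos
        peptide.append(_CODON_TABLE.get(codon, "X"))
        pos += 3
    raise ValueError("open reading frame runs off the transcript without a stop codon")


def build_fusion_transcript(
    genome: GenomeAssembly,
    gene5: GeneModel,
    last_exon5: int,
    gene3: GeneModel,
    first_exon3: int,
) -> FusionTranscript:
    """Splice retained 5' exons (1..last_exon5) to retained 3' exons
    (first_exon3..n), both counted in transcription order, 1-based."""
    if not (1 <= last_exon5 <= gene5.n_exons):
        raise ValueError(f"last_exon5 {last_exon5} out of range for {gene5.gene_id}")
    if not (1 <= first_exon3 <= gene3.n_exons):
        raise ValueError(f"first_exon3 {first_exon3} out of range for {gene3.gene_id}")
    tx5 = spliced_sequence(genome, gene5)
    tx3 = spliced_sequence(genome, gene3)
    keep5 = sum(e - s for s, e in gene5.exons_tx_order()[:last_exon5])
    skip3 = sum(e - s for s, e in gene3.exons_tx_order()[: first_exon3 - 1])
    return FusionTranscript(
        sequence=tx5[:keep5] + tx3[skip3:],
        junction_offset=keep5,
        gene5_id=gene5.gene_id,
        gene3_id=gene3.gene_id,
        gene5_cds_start=gene5.cds_start,
        gene3_cds_start=gene3.cds_start,
        skipped_3p_length=skip3,
    )


def predict_fusion_orfs(ft: FusionTranscript) -> list[OrfPrediction]:
    """Predict the readthrough and internal-start products of a fusion.

    The readthrough ORF starts at the 5' partner's native ATG and runs to
    the first in-frame stop; residues whose codon touches the junction or
    anything 3' of it count as novel. The internal-start ORF uses the
    first ATG at or after the junction that is in frame with the 3'
    partner's native stop codon; when no such ATG exists that product is
    simply absent. No ranking by translatability is attempted — whether
    the ribosome actually selects either ORF is biology outside the
    predictor's scope.
    """
    seq = ft.sequence
    j = ft.junction_offset
    if ft.gene5_cds_start is None:
        raise ValueError("gene5 cds_start is required for ORF prediction")
    cds5 = ft.gene5_cds_start
    if cds5 >= j:
        raise ValueError("5' partner start codon must lie upstream of the junction")
    if seq[cds5 : cds5 + 3] != "ATG":
        raise ValueError(f"no ATG at the declared 5' start codon (offset {cds5})")

    predictions: list[OrfPrediction] = []
    peptide, stop = _translate_to_stop(seq, cds5)
    novel = sum(
        1 for i in range(cds5, stop, 3) if i + 3 > j  # codon touches or passes the junction
    )
    in_frame: bool | None = None
    anchor3 = None
    if ft.gene3_cds_start is not None:
        # 3' partner's native reading frame anchored in fusion coordinates
        anchor3 = j - ft.skipped_3p_length + ft.gene3_cds_start
        in_frame = (cds5 - anchor3) % 3 == 0
    predictions.append(
        OrfPrediction(
            kind="truncated_5p_readthrough",
            start_offset=cds5,
            stop_offset=stop,
            peptide=peptide,
            mass_kda=peptide_mass(peptide),
            novel_aa_count=novel,
            in_frame=in_frame,
        )
    )

    if anchor3 is not None:
        frame3 = anchor3 % 3
        start3 = None
        for pos in range(j, len(seq) - 2):
            if seq[pos : pos + 3] == "ATG" and pos % 3 == frame3:
                start3 = pos
                break
        if start3 is not None:
            pep3, stop3 = _translate_to_stop(seq, start3)
            predictions.append(
                OrfPrediction(
                    kind="internal_start_3p",
                    start_offset=start3,
                    stop_offset=stop3,
                    peptide=pep3,
                    mass_kda=peptide_mass(pep3),
                )
            )
    return predictions


def breakpoint_offsets(
    bp5: tuple[str, int],
    bp3: tuple[str, int],
    gene5: GeneModel,
    gene3: GeneModel,
    last_exon5: int,
    first_exon3: int,
) -> BreakpointOffsets:
    """Distances from genomic breakpoints to the flanking retained exons.

    ``dist_to_5p_exon_end`` measures along the transcription direction
    from the last base of the last retained 5' exon to the breakpoint;
    ``dist_to_3p_exon_start`` from the breakpoint to the first base of
    the first retained 3' exon. A breakpoint at the exon's terminal base
    yields 0; a breakpoint strictly inside an exon is an error (the
    breakpoints of a splicing-compatible fusion are intronic).
    """
    chrom5, pos5 = bp5
    chrom3, pos3 = bp3
    if chrom5 != gene5.chrom or chrom3 != gene3.chrom:
        raise ValueError("breakpoint chromosome does not match its gene model")

    exons5 = gene5.exons_tx_order()
    s5, e5 = exons5[last_exon5 - 1]
    d5 = pos5 - (e5 - 1) if gene5.strand == "+" else s5 - pos5
    if d5 < 0:
        raise ValueError("5' breakpoint lies inside or upstream of the retained exon")
    if s5 <= pos5 < e5 and d5 != 0:
        raise ValueError("5' breakpoint falls inside an exon")
    if last_exon5 < gene5.n_exons:
        i_s, i_e = gene5.intron_tx(last_exon5)
        terminal = (e5 - 1) if gene5.strand == "+" else s5
        if not (i_s <= pos5 < i_e or pos5 == terminal):
            raise ValueError("5' breakpoint outside the expected intron")

    exons3 = gene3.exons_tx_order()
    s3, e3 = exons3[first_exon3 - 1]
    d3 = (s3 - pos3) if gene3.strand == "+" else pos3 - (e3 - 1)
    if d3 < 0:
        raise ValueError("3' breakpoint lies inside or downstream of the retained exon")
    if s3 <= pos3 < e3 and d3 != 0:
        raise ValueError("3' breakpoint falls inside an exon")
    if first_exon3 > 1:
        i_s, i_e = gene3.intron_tx(first_exon3 - 1)
        first_base = s3 if gene3.strand == "+" else (e3 - 1)
        if not (i_s <= pos3 < i_e or pos3 == first_base):
            raise ValueError("3' breakpoint outside the expected intron")

    return BreakpointOffsets(
        breakpoint5=bp5, breakpoint3=bp3, dist_to_5p_exon_end=d5, dist_to_3p_exon_start=d3
    )


def microhomology(
    seq5_context: str,
    junction5: int,
    seq3_context: str,
    junction3: int,
    max_probe: int = 15,
) -> MicrohomologyResult:
    """Length of identical sequence shared by both partners at a breakpoint.

    Probes up to ``max_probe`` bases immediately 5' of each junction
    point (and symmetrically 3') for the longest run that is identical
    between the two partners; 0 (side 'none') when the first bases
    already differ. Absence of microhomology is the signature of
    non-homologous end joining. Symmetric in its two partners.
    """
    if junction5 < max_probe or junction3 < max_probe:
        raise ValueError("context too short 5' of a junction point")
    if len(seq5_context) - junction5 < max_probe or len(seq3_context) - junction3 < max_probe:
        raise ValueError("context too short 3' of a junction point")
    a, b = seq5_context.upper(), seq3_context.upper()
    h5 = 0
    while h5 < max_probe and a[junction5 - h5 - 1] == b[junction3 - h5 - 1]:
        h5 += 1
    h3 = 0
    while h3 < max_probe and a[junction5 + h3] == b[junction3 + h3]:
        h3 += 1
    if h5 == 0 and h3 == 0:
        return MicrohomologyResult(0, "none")
    return MicrohomologyResult(max(h5, h3), "5p" if h5 >= h3 else "3p")


def annotation_report(
    orfs: list[OrfPrediction],
    offsets: BreakpointOffsets | None = None,
    micro: MicrohomologyResult | None = None,
) -> dict:
    """JSON-ready annotation report; masses in kDa (2 decimals + rounded)."""
    report: dict = {"orfs": []}
    for orf in orfs:
        report["orfs"].append(
            {
                "kind": orf.kind,
                "start_offset": orf.start_offset,
                "stop_offset": orf.stop_offset,
                "peptide_length": len(orf.peptide),
                "mass_kda": round(orf.mass_kda, 2),
                "mass_kda_rounded": int(round(orf.mass_kda)),
                "novel_aa_count": orf.novel_aa_count,
                "in_frame": orf.in_frame,
            }
        )
    if offsets is not None:
        report["breakpoints"] = {
            "breakpoint5": f"{offsets.breakpoint5[0]}:{offsets.breakpoint5[1] + 1:,}",
            "breakpoint3": f"{offsets.breakpoint3[0]}:{offsets.breakpoint3[1] + 1:,}",
            "dist_to_5p_exon_end": offsets.dist_to_5p_exon_end,
            "dist_to_3p_exon_start": offsets.dist_to_3p_exon_start,
        }
    if micro is not None:
        report["microhomology"] = {"length": micro.length, "side": micro.side}
    return report
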