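"""Junction-spanning read counting against a known junction template.

Templates come from validated junction sequences (in practice,
Sanger-sequenced RT-PCR amplicons; on synthetic data, the engineered
fusion transcript). A previously unmappable read counts as a junction
read only when its mate lies in a parental gene, its best placement on
the template spans the junction with at least ``min_flank`` bases on
each side, and mismatches respect the tolerance — none at all inside the
flanking window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import revcomp
from .read_mapping import Read


@dataclass(frozen=True)
class JunctionTemplate:
    """A validated fusion junction sequence.

    ``junction_offset`` is the 0-based index of the first base 3' of the
    junction.
    """

    sequence: str
    junction_offset: int
    gene5_id: str
    gene3_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)):
            raise ValueError("junction_offset must fall strictly inside the template")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class JunctionCriteria:
    min_flank: int = 6
    max_mismatches: int = 2
    flank_mismatch_allowance: int = 0
    require_mate_in_parental: bool = True

    def __post_init__(self) -> None:
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")
        if self.flank_mismatch_allowance > self.max_mismatches:
            raise ValueError("flank allowance cannot exceed total mismatch tolerance")


@dataclass(frozen=True)
class SupportSummary:
    """Combined chimeric-pair + junction-read support for one fusion."""

    chimeric_pair_count: int
    junction_read_count: int

    @property
    def display(self) -> str:
        """'c+j' form, e.g. '7+19' for 7 chimeric pairs and 19 junction reads."""
        return f"{self.chimeric_pair_count}+{self.junction_read_count}"


@dataclass(frozen=True)
class JunctionPlacement:
    position: int
    strand: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # template coordinates


def _placements(read_seq: str, template: str, max_mm: int) -> list[JunctionPlacement]:
    out = []
    for strand, q in (("+", read_seq), ("-", revcomp(read_seq))):
        for pos in range(len(template) - len(q) + 1):
            window = template[pos : pos + len(q)]
            mism = tuple(pos + i for i, (x, y) in enumerate(zip(q, window)) if x != y)
            if len(mism) <= max_mm:
                out.append(JunctionPlacement(pos, strand, len(mism), mism))
    return out


def map_junction_read(
    read: Read | str,
    template: JunctionTemplate,
    mate_in_parental: bool,
    criteria: JunctionCriteria = JunctionCriteria(),
) -> tuple[bool, JunctionPlacement | None]:
    """Decide whether one read counts as a junction read.

    The read is placed on the template by exhaustive Hamming scan (both
    strands); the fewest-mismatch placement is used and a tie between
    distinct placements rejects the read as ambiguous. Acceptance then
    requires: mate in a parental gene (when the criteria demand it), at
    least ``min_flank`` aligned bases on each side of the junction, total
    mismatches within tolerance, and no mismatch inside the
    +-``min_flank`` window around the junction (beyond the configured
    allowance).
    """
    seq = read.bases if isinstance(read, Read) else read
    j = template.junction_offset
    if j < criteria.min_flank or len(template.sequence) - j < criteria.min_flank:
        warnings.warn(
            f"template {template.name or template.gene5_id}-{template.gene3_id} too "
            f"short on one side of the junction for min_flank={criteria.min_flank}; "
            "every read will be rejected",
            stacklevel=2,
        )
        return False, None
    if criteria.require_mate_in_parental and not mate_in_parental:
        return False, None
    placements = _placements(seq, template.sequence, criteria.max_mismatches)
    if not placements:
        return False, None
    best_mm = min(p.mismatch_count for p in placements)
    best = [p for p in placements if p.mismatch_count == best_mm]
    if len(best) > 1:
        return False, None  # ambiguous placement on the template
    p = best[0]
    left = j - p.position
    right = p.position + len(seq) - j
    if left < criteria.min_flank or right < criteria.min_flank:
        return False, p
    flank_lo, flank_hi = j - criteria.min_flank, j + criteria.min_flank
    flank_mm = sum(1 for m in p.mismatch_positions if flank_lo <= m < flank_hi)
    if flank_mm > criteria.flank_mismatch_allowance:
        return False, p
    return True, p


def count_junction_support(
    unmapped_reads: Iterable[Read],
    template: JunctionTemplate,
    mate_in_parental: Mapping[str, bool],
    criteria: JunctionCriteria = JunctionCriteria(),
    chimeric_pair_count: int = 0,
) -> SupportSummary:
    """Count accepted junction reads; each read counts at most once."""
    count = 0
    for read in unmapped_reads:
        ok, _ = map_junction_read(
            read, template, mate_in_parental.get(read.id, False), criteria
        )
        if ok:
            count += 1
    return SupportSummary(
        chimeric_pair_count=chimeric_pair_count, junction_read_count=count
    )


def orient_partners(candidate_genes: tuple[str, str], template: JunctionTemplate) -> tuple[str, str]:
    """Order an unordered candidate gene pair using a junction template.

    Pair evidence alone cannot order the partners; the template (derived
    from the sequenced junction) fixes which gene contributes the 5'
    part. A palindromic template, for which both orientations align, is
    rejected as ambiguous and demands manual resolution.
    """
    if set(candidate_genes) != {template.gene5_id, template.gene3_id}:
        raise ValueError(
            f"template genes ({template.gene5_id}, {template.gene3_id}) do not match "
            f"candidate pair {candidate_genes}"
        )
    if revcomp(template.sequence) == template.sequence:
        raise ValueError(
            "palindromic junction template: both orientations align; resolve manually"
        )
    return template.gene5_id, template.gene3_id


def write_templates(templates: Iterable[JunctionTemplate], path: str | Path) -> None:
    """Write templates as FASTA with the junction offset in the description.

    The description carries ``junction=<int>`` (0-based index of the
    first base 3' of the junction) plus the ordered parental gene ids.
    """
    records = []
    for t in templates:
        rec = SeqRecord(
            Seq(t.sequence),
            id=t.name or f"{t.gene5_id}-{t.gene3_id}",
            description=f"junction={t.junction_offset} gene5={t.gene5_id} gene3={t.gene3_id}",
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


def read_templates(path: str | Path) -> list[JunctionTemplate]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split("=", 1) for part in rec.description.split() if "=" in part
        )
        if "junction" not in fields:
            raise ValueError(f"{rec.id}: template lacks junction=<int> in description")
        out.append(
            JunctionTemplate(
                sequence=str(rec.seq),
                junction_offset=int(fields["junction"]),
                gene5_id=fields.get("gene5", ""),
                gene3_id=fields.get("gene3", ""),
                name=rec.id,
            )
        )
    return out
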