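"""Aggregate inconsistent read pairs into fusion candidates and filter them.

A fusion call must survive the full cascade: clonal-duplicate removal
(mate start positions at least ``min_separation`` bp apart), a minimum of
two supporting chimeric pairs, predominance of a single strand
combination, exclusion of overlapping gene pairs, exclusion of homologous
gene pairs (shared k-mer fraction), and a remap check ensuring no
supporting read has an equal-or-better placement elsewhere.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .genome_model import (
    Annotation,
    GenomeAssembly,
    GenePairRelation,
    classify_gene_pair,
    shared_kmer_fraction,
    spliced_sequence,
)

FILTER_ORDER = ("dedup", "min_support", "strand", "overlap", "homology", "remap")


@dataclass(frozen=True)
class MatePlacement:
    """One mate's placement on (or within) a gene."""

    gene_id: str
    start: int
    strand: str  # sense-relative to the gene
    mismatches: int = 0
    genomic: bool = False  # start is genomic rather than transcript-relative


@dataclass(frozen=True)
class SupportingPair:
    """One chimeric read pair; placements follow the candidate's gene order."""

    read_id: str
    a: MatePlacement
    b: MatePlacement

    @property
    def strand_combo(self) -> str:
        return self.a.strand + self.b.strand

    @property
    def starts(self) -> tuple[int, int]:
        return (self.a.start, self.b.start)


@dataclass
class ChimericEvidence:
    """All chimeric read pairs connecting one (unordered) gene pair."""

    genes: tuple[str, str]  # sorted lexicographically
    pairs: list[SupportingPair] = field(default_factory=list)

    def strand_combos(self) -> Counter:
        return Counter(p.strand_combo for p in self.pairs)

    def distinct_starts(self) -> int:
        return len({p.starts for p in self.pairs})


@dataclass(frozen=True)
class FilterConfig:
    min_support: int = 2
    min_separation: int = 5
    predominance_threshold: float = 0.8
    homology_k: int = 31
    homology_threshold: float = 0.05
    neighbor_max_gap: int = 100_000


@dataclass(frozen=True)
class CohortSelectionRule:
    """Candidate prioritization across a cohort."""

    min_samples: int = 2
    min_pairs_single_sample: int = 3
    cancer_gene_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.min_samples < 1 or self.min_pairs_single_sample < 1:
            raise ValueError("selection thresholds must be >= 1")


@dataclass
class FusionCandidate:
    genes: tuple[str, str]
    support: int  # surviving pairs after dedup
    distinct_starts: int
    modal_strand_combo: str | None
    strand_fraction: float
    relation: GenePairRelation | None
    verdicts: dict[str, bool]
    status: str  # 'pass' or 'filtered'
    reason: str | None  # first failing filter

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def collect_evidence(
    observations: Iterable[tuple[str, str, MatePlacement, MatePlacement]],
) -> dict[tuple[str, str], ChimericEvidence]:
    """Group inconsistent pairs by unordered gene pair.

    Each observation is ``(read_id, _, placement_1, placement_2)`` for a
    pair already classed inconsistent (mates in two distinct,
    non-overlapping genes); transcriptome- and genome-tier evidence is
    merged simply by feeding both in.
    """
    out: dict[tuple[str, str], ChimericEvidence] = {}
    for read_id, _, p1, p2 in observations:
        if p1.gene_id == p2.gene_id:
            raise ValueError(f"{read_id}: mates in the same gene are not chimeric")
        if p1.gene_id < p2.gene_id:
            key, a, b = (p1.gene_id, p2.gene_id), p1, p2
        else:
            key, a, b = (p2.gene_id, p1.gene_id), p2, p1
        ev = out.setdefault(key, ChimericEvidence(genes=key))
        ev.pairs.append(SupportingPair(read_id=read_id, a=a, b=b))
    return out


def dedup_clonal(ev: ChimericEvidence, min_separation: int = 5) -> ChimericEvidence:
    """Collapse clonal PCR duplicates among supporting pairs.

    Pairs are scanned in read-id order; a pair whose two mate starts are
    both within ``min_separation`` bp of an already-retained
    representative is dropped. Survivors therefore pairwise differ by at
    least ``min_separation`` bp in at least one mate. Invariant to the
    input ordering of pairs.
    """
    retained: list[SupportingPair] = []
    for pair in sorted(ev.pairs, key=lambda p: p.read_id):
        dup = any(
            abs(pair.a.start - rep.a.start) < min_separation
            and abs(pair.b.start - rep.b.start) < min_separation
            for rep in retained
        )
        if not dup:
            retained.append(pair)
    return ChimericEvidence(genes=ev.genes, pairs=retained)


def strand_filter(
    ev: ChimericEvidence, predominance_threshold: float = 0.8
) -> tuple[bool, str | None, float]:
    """Require one predominant strand combination among supporting pairs.

    Returns (verdict, modal combination, modal fraction); a tie between
    combinations fails the filter.
    """
    combos = ev.strand_combos()
    if not combos:
        return False, None, 0.0
    ranked = combos.most_common()
    top_combo, top_count = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top_count:
        return False, None, top_count / len(ev.pairs)
    fraction = top_count / len(ev.pairs)
    return fraction >= predominance_threshold, top_combo, fraction


def apply_filter_cascade(
    ev: ChimericEvidence,
    annotation: Annotation,
    genome: GenomeAssembly,
    config: FilterConfig = FilterConfig(),
    remap_check: Callable[[SupportingPair], bool] | None = None,
) -> FusionCandidate:
    """Run the full filter cascade on one evidence group.

    Each filter is a pure predicate on the (deduplicated) evidence, so
    the pass/fail outcome is order-insensitive; only the recorded
    ``reason`` reflects the canonical order. ``remap_check`` receives
    each surviving pair and must confirm that neither mate has an
    equal-or-better placement elsewhere; omit it to skip that filter.
    """
    deduped = dedup_clonal(ev, config.min_separation)
    verdicts: dict[str, bool] = {}
    verdicts["dedup"] = True  # dedup itself never fails, it reduces support
    verdicts["min_support"] = len(deduped.pairs) >= config.min_support
    strand_ok, modal, fraction = strand_filter(deduped, config.predominance_threshold)
    verdicts["strand"] = strand_ok

    ga, gb = annotation[ev.genes[0]], annotation[ev.genes[1]]
    relation = classify_gene_pair(ga, gb, config.neighbor_max_gap)
    verdicts["overlap"] = relation.kind != "overlapping"

    seq_a = spliced_sequence(genome, ga)
    seq_b = spliced_sequence(genome, gb)
    if min(len(seq_a), len(seq_b)) < config.homology_k:
        verdicts["homology"] = True  # too short to assess; do not exclude
    else:
        frac = shared_kmer_fraction(seq_a, seq_b, config.homology_k)
        verdicts["homology"] = frac < config.homology_threshold

    if remap_check is None:
        verdicts["remap"] = True
    else:
        verdicts["remap"] = all(remap_check(pair) for pair in deduped.pairs)

    reason = next((name for name in FILTER_ORDER if not verdicts[name]), None)
    return FusionCandidate(
        genes=ev.genes,
        support=len(deduped.pairs),
        distinct_starts=deduped.distinct_starts(),
        modal_strand_combo=modal,
        strand_fraction=fraction,
        relation=relation,
        verdicts=verdicts,
        status="pass" if reason is None else "filtered",
        reason=reason,
    )


def select_candidates(
    per_sample: Mapping[str, Sequence[FusionCandidate]],
    rule: CohortSelectionRule = CohortSelectionRule(),
) -> pd.DataFrame:
    """Prioritize passing candidates across a cohort.

    A candidate is selected when it recurs in at least ``min_samples``
    samples, or reaches ``min_pairs_single_sample`` surviving pairs in
    any one sample, or involves a cancer-catalog gene. Sorted by
    (samples desc, max support desc, gene pair).
    """
    seen: dict[tuple[str, str], dict] = {}
    for sample, candidates in per_sample.items():
        for cand in candidates:
            if not cand.passed:
                continue
            entry = seen.setdefault(
                cand.genes, {"samples": set(), "max_support": 0}
            )
            entry["samples"].add(sample)
            entry["max_support"] = max(entry["max_support"], cand.support)
    rows = []
    for genes, entry in seen.items():
        n_samples = len(entry["samples"])
        in_catalog = bool(set(genes) & rule.cancer_gene_ids)
        selected = (
            n_samples >= rule.min_samples
            or entry["max_support"] >= rule.min_pairs_single_sample
            or in_catalog
        )
        rows.append(
            {
                "gene_a": genes[0],
                "gene_b": genes[1],
                "n_samples": n_samples,
                "max_support": entry["max_support"],
                "cancer_gene": in_catalog,
                "selected": selected,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_samples", "max_support", "cancer_gene", "selected"],
    )
    if len(df):
        df = df.sort_values(
            by=["n_samples", "max_support", "gene_a", "gene_b"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)
    return df


def candidate_table(candidates: Sequence[FusionCandidate], annotation: Annotation) -> pd.DataFrame:
    """Flat per-candidate report table."""
    rows = []
    for c in candidates:
        ga, gb = annotation[c.genes[0]], annotation[c.genes[1]]
        rows.append(
            {
                "gene_a": c.genes[0],
                "gene_b": c.genes[1],
                "chrom_a": ga.chrom,
                "chrom_b": gb.chrom,
                "class": c.relation.kind if c.relation else "NA",
                "support_pairs": c.support,
                "distinct_starts": c.distinct_starts,
                "strand_combo": c.modal_strand_combo or "NA",
                "strand_fraction": round(c.strand_fraction, 3),
                "status": c.status,
                "reason": c.reason or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "chrom_a",
            "chrom_b",
            "class",
            "support_pairs",
            "distinct_starts",
            "strand_combo",
            "strand_fraction",
            "status",
            "reason",
        ],
    )
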