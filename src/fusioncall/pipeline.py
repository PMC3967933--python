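"""End-to-end orchestration of the fusion discovery workflow.

Stages: simulate (toy genome + engineered fusion + reads with truth),
discover (QC -> transcriptome tier -> genome tier -> chimeric evidence ->
filter cascade), junction (count junction-spanning reads against a
template), report (merge candidate class, combined support, ORF
annotation and recurrence into one table). Every run emits a manifest
with its config snapshot and input checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .chimera_detection import (
    ChimericEvidence,
    FusionCandidate,
    MatePlacement,
    SupportingPair,
    apply_filter_cascade,
    candidate_table,
    collect_evidence,
)
from .config import PipelineConfig
from .genome_model import Annotation, GenomeAssembly, spliced_sequence
from .junction_support import (
    JunctionTemplate,
    SupportSummary,
    count_junction_support,
    write_templates,
)
from .read_mapping import (
    AlignmentRecord,
    BruteForceMapper,
    PairClass,
    Read,
    ReferenceIndex,
    classify_pair,
    map_read,
    qc_reads,
    read_fastq,
    remap_validate,
    write_fastq,
)
from .synthetic_data import (
    FusionTruth,
    ReadSimConfig,
    engineer_fusion,
    make_toy_reference,
    simulate_read_pairs,
)


@dataclass
class SimulatedStudy:
    """In-memory result of the simulation stage, with full ground truth."""

    reference: GenomeAssembly  # the *reference* assembly (no derivative chromosome)
    annotation: Annotation
    fusion_truth: FusionTruth
    fusion_transcript: str
    template: JunctionTemplate
    transcripts: dict[str, str]
    reads1: list[Read]
    reads2: list[Read]
    truth_table: pd.DataFrame


@dataclass
class PairObservation:
    read_id: str
    pair_class: PairClass
    placement1: MatePlacement | None = None
    placement2: MatePlacement | None = None
    aln1: AlignmentRecord | None = None
    aln2: AlignmentRecord | None = None


@dataclass
class DiscoveryResult:
    candidates: list[FusionCandidate]
    table: pd.DataFrame
    attrition: dict[str, int]
    evidence: dict[tuple[str, str], ChimericEvidence]
    unmapped_reads: list[Read]
    mate_genes: dict[str, set]  # read id -> genes any mapped mate resolved to


def simulate_study(config: PipelineConfig) -> SimulatedStudy:
    """Build the standard synthetic study: one inter-chromosomal engineered
    fusion plus read-through, overlapping and homologous decoy chimeras.

    Reads are simulated from every parental transcript, the fusion
    transcript, and three artifact chimera transcripts that exercise the
    decoy filters (read-through of the adjacent pair, a chimera joining
    the overlapping pair, and a chimera joining the homologous pair).
    """
    if config.sim_genes_per_chrom < 3:
        raise ValueError("simulation needs >= 3 genes per chromosome (decoys occupy two)")
    genome, annotation = make_toy_reference(
        n_chrom=config.sim_n_chrom,
        genes_per_chrom=config.sim_genes_per_chrom,
        exons_per_gene=config.sim_exons_per_gene,
        seed=config.seed,
    )
    gene5 = f"G1_{config.sim_genes_per_chrom}"
    gene3 = f"G2_{config.sim_genes_per_chrom}"
    g3 = annotation[gene3]
    intron3 = min(2, g3.n_exons - 1)
    der_assembly, fusion_model, truth = engineer_fusion(
        genome, annotation, gene5, gene3, 1, intron3, seed=config.seed + 1
    )
    fusion_tx = spliced_sequence(der_assembly, fusion_model)

    transcripts = {g.gene_id: spliced_sequence(genome, g) for g in annotation}
    sim_transcripts = dict(transcripts)
    sim_transcripts[f"FUS|{gene5}|{gene3}"] = fusion_tx
    # artifact chimeras exercising the decoy filters
    a, b = "G1_1", "G1_2"
    sim_transcripts[f"RT|{a}|{b}"] = transcripts[a] + transcripts[b]
    host, nested = "G2_2", "G2_2_OV"
    host_exon1 = annotation[host].exons_tx_order()[0]
    keep = host_exon1[1] - host_exon1[0]
    sim_transcripts[f"OVL|{host}|{nested}"] = transcripts[host][:keep] + transcripts[nested]
    src, hom = "G2_1", "G2_1_HOM"
    src_exon1 = annotation[src].exons_tx_order()[0]
    keep = src_exon1[1] - src_exon1[0]
    skip = annotation[hom].exons_tx_order()[0][1] - annotation[hom].exons_tx_order()[0][0]
    sim_transcripts[f"HOM|{src}|{hom}"] = transcripts[src][:keep] + transcripts[hom][skip:]

    sim_cfg = ReadSimConfig(
        read_length=config.sim_read_length,
        fragment_mean=config.sim_fragment_mean,
        fragment_sd=config.sim_fragment_sd,
        depth=config.sim_depth,
        substitution_error_rate=config.sim_error_rate,
        clonal_duplicate_rate=config.sim_duplicate_rate,
        rng_seed=config.seed + 2,
    )
    reads1, reads2, truth_table = simulate_read_pairs(sim_transcripts, sim_cfg)
    template = JunctionTemplate(
        sequence=fusion_tx,
        junction_offset=truth.junction_offset,
        gene5_id=gene5,
        gene3_id=gene3,
        name=f"{gene5}-{gene3}",
    )
    return SimulatedStudy(
        reference=genome,
        annotation=annotation,
        fusion_truth=truth,
        fusion_transcript=fusion_tx,
        template=template,
        transcripts=sim_transcripts,
        reads1=reads1,
        reads2=reads2,
        truth_table=truth_table,
    )


def _unique_best(records: Sequence[AlignmentRecord]) -> AlignmentRecord | None:
    """The single best placement, or None when absent or tied (not unique)."""
    if len(records) == 1 and records[0].is_unique:
        return records[0]
    return None


def _sense_placement(
    aln: AlignmentRecord, gene_id: str, annotation: Annotation
) -> MatePlacement:
    """Convert an alignment to a gene-relative placement.

    Transcriptome-tier strands are already sense-relative (the reference
    is the sense transcript); genome-tier strands are flipped for genes
    on the minus strand so strand combinations compare across tiers.
    """
    if aln.reference in annotation:
        return MatePlacement(
            gene_id=gene_id,
            start=aln.position,
            strand=aln.strand,
            mismatches=aln.mismatch_count,
            genomic=False,
        )
    gene = annotation[gene_id]
    sense = "+" if aln.strand == gene.strand else "-"
    return MatePlacement(
        gene_id=gene_id,
        start=aln.position,
        strand=sense,
        mismatches=aln.mismatch_count,
        genomic=True,
    )


def discover(
    reads1: Sequence[Read],
    reads2: Sequence[Read],
    genome: GenomeAssembly,
    annotation: Annotation,
    config: PipelineConfig = PipelineConfig(),
) -> DiscoveryResult:
    """Run QC, two-tier mapping, evidence collection and the filter cascade."""
    attrition: dict[str, int] = {}
    by_id1 = {r.id: r for r in reads1}
    by_id2 = {r.id: r for r in reads2}
    attrition["input_pairs"] = len(set(by_id1) | set(by_id2))

    kept1, _ = qc_reads(reads1, config.min_quality, config.min_length)
    kept2, _ = qc_reads(reads2, config.min_quality, config.min_length)
    k1 = {r.id: r for r in kept1}
    k2 = {r.id: r for r in kept2}
    pair_ids = sorted(set(k1) & set(k2))
    attrition["pairs_after_qc"] = len(pair_ids)

    transcripts = {g.gene_id: spliced_sequence(genome, g) for g in annotation}
    tindex = ReferenceIndex(transcripts, config.seed_length)
    gindex = ReferenceIndex(genome.sequences, config.seed_length)

    observations: list[PairObservation] = []
    unmapped_reads: list[Read] = []
    mate_genes: dict[str, set] = {}
    reads_by_mate: dict[tuple[str, int], Read] = {}

    for rid in pair_ids:
        r1, r2 = k1[rid], k2[rid]
        reads_by_mate[(rid, 1)] = r1
        reads_by_mate[(rid, 2)] = r2
        a1 = _unique_best(map_read(tindex, r1, config.transcriptome_max_mismatches))
        a2 = _unique_best(map_read(tindex, r2, config.transcriptome_max_mismatches))
        cls, ga, gb = classify_pair(
            a1, a2, annotation, config.transcriptome_max_mismatches
        )
        if cls in (PairClass.ONE_END_MAPPED, PairClass.UNMAPPED):
            # genome tier for mates the transcriptome could not place
            if a1 is None:
                a1 = _unique_best(map_read(gindex, r1, config.genome_max_mismatches))
            if a2 is None:
                a2 = _unique_best(map_read(gindex, r2, config.genome_max_mismatches))
            cls, ga, gb = classify_pair(a1, a2, annotation, config.genome_max_mismatches)

        genes_here = {g for g in (ga, gb) if g is not None}
        if genes_here:
            mate_genes.setdefault(rid, set()).update(genes_here)
        if a1 is None:
            unmapped_reads.append(r1)
        if a2 is None:
            unmapped_reads.append(r2)

        obs = PairObservation(read_id=rid, pair_class=cls, aln1=a1, aln2=a2)
        if cls is PairClass.INCONSISTENT_TWO_GENES:
            assert ga is not None and gb is not None
            obs.placement1 = _sense_placement(a1, ga, annotation)
            obs.placement2 = _sense_placement(a2, gb, annotation)
        observations.append(obs)

    for cls in PairClass:
        attrition[cls.value] = sum(1 for o in observations if o.pair_class is cls)

    evidence = collect_evidence(
        (o.read_id, o.pair_class.value, o.placement1, o.placement2)
        for o in observations
        if o.pair_class is PairClass.INCONSISTENT_TWO_GENES
    )
    attrition["evidence_gene_pairs"] = len(evidence)

    # remap validation: no supporting read may have an equal-or-better
    # placement anywhere else (its own gene locus does not count)
    all_refs = {**transcripts, **genome.sequences}
    bf = BruteForceMapper(all_refs)
    alignments_by_mate: dict[tuple[str, int], list[AlignmentRecord]] = {}
    for o in observations:
        for aln in (o.aln1, o.aln2):
            if aln is not None:
                alignments_by_mate.setdefault((o.read_id, aln.mate), []).append(aln)

    def same_locus_for(gene_id: str):
        gene = annotation[gene_id]

        def check(name: str, pos: int, strand: str) -> bool:
            if name == gene_id:
                return True
            return name == gene.chrom and pos < gene.end and pos + 1 > gene.start

        return check

    def remap_check(pair: SupportingPair) -> bool:
        for placement in (pair.a, pair.b):
            for aln in alignments_by_mate.get((pair.read_id, 1), []) + alignments_by_mate.get(
                (pair.read_id, 2), []
            ):
                if _matches(aln, placement, annotation):
                    read = reads_by_mate[(pair.read_id, aln.mate)]
                    ok = remap_validate(
                        read.bases, bf, aln, same_locus=same_locus_for(placement.gene_id)
                    )
                    if not ok:
                        return False
        return True

    candidates = [
        apply_filter_cascade(
            ev, annotation, genome, config.filter_config(), remap_check=remap_check
        )
        for ev in (evidence[k] for k in sorted(evidence))
    ]
    attrition["candidates_pass"] = sum(1 for c in candidates if c.passed)
    table = candidate_table(candidates, annotation)
    return DiscoveryResult(
        candidates=candidates,
        table=table,
        attrition=attrition,
        evidence=evidence,
        unmapped_reads=unmapped_reads,
        mate_genes=mate_genes,
    )


def _matches(aln: AlignmentRecord, placement: MatePlacement, annotation: Annotation) -> bool:
    if aln.reference in annotation:
        return aln.reference == placement.gene_id and aln.position == placement.start
    return (
        placement.genomic
        and aln.position == placement.start
        and aln.reference == annotation[placement.gene_id].chrom
    )


def junction_stage(
    discovery: DiscoveryResult,
    template: JunctionTemplate,
    config: PipelineConfig = PipelineConfig(),
) -> SupportSummary:
    """Count junction reads for one template among the pipeline's unmapped reads."""
    parental = {template.gene5_id, template.gene3_id}
    mate_ok = {
        rid: bool(genes & parental) for rid, genes in discovery.mate_genes.items()
    }
    key = tuple(sorted(parental))
    chimeric = 0
    for cand in discovery.candidates:
        if cand.genes == key:
            chimeric = cand.support
    return count_junction_support(
        discovery.unmapped_reads,
        template,
        mate_ok,
        config.junction_criteria(),
        chimeric_pair_count=chimeric,
    )


def truth_straddler_count(
    study: SimulatedStudy, discovery: DiscoveryResult, config: PipelineConfig
) -> int:
    """Ground-truth junction-read count for the study's engineered fusion.

    Counts reads whose true source interval on the fusion transcript
    straddles the junction by at least the flank floor on both sides,
    whose mate lies entirely in one parental gene, and which the two-tier
    mapper left unplaced (the junction criterion applies only to
    previously unmappable reads; a marginal-flank straddler occasionally
    matches genomic context within the genome tier's tolerance and is
    consumed upstream).
    """
    j = study.fusion_truth.junction_offset
    rl = config.sim_read_length
    mf = config.junction_min_flank
    unmapped = {(r.id, r.mate) for r in discovery.unmapped_reads}
    fus = study.truth_table[study.truth_table.transcript.str.startswith("FUS|")]
    count = 0
    for _, row in fus.iterrows():
        ends = (
            (row.fragment_start, row.fragment_start + rl),
            (row.fragment_end - rl, row.fragment_end),
        )
        for mate, ((a, b), (oa, ob)) in enumerate(
            ((ends[0], ends[1]), (ends[1], ends[0])), start=1
        ):
            if (
                a <= j - mf
                and b >= j + mf
                and not (oa < j < ob)
                and (row.read_id, mate) in unmapped
            ):
                count += 1
    return count


def build_report(
    candidates: pd.DataFrame,
    junction_summaries: Mapping[tuple[str, str], SupportSummary] | None = None,
    recurrence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge candidate class, combined 'c+j' support and recurrence percentages."""
    report = candidates.copy()
    junction_summaries = junction_summaries or {}
    support = []
    for _, row in report.iterrows():
        key = tuple(sorted((row["gene_a"], row["gene_b"])))
        summary = junction_summaries.get(key)
        support.append(summary.display if summary is not None else "NA")
    report["support"] = support
    if recurrence is not None and len(recurrence):
        pivot = recurrence.pivot_table(
            index="fusion", columns="group", values="percent", aggfunc="first"
        )
        fusion_ids = report["gene_a"] + "-" + report["gene_b"]
        for group in pivot.columns:
            report[f"pct_{group}"] = [
                pivot.loc[f, group] if f in pivot.index else pd.NA for f in fusion_ids
            ]
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: Path, config: PipelineConfig, files: Mapping[str, Path], extra: dict | None = None
) -> None:
    manifest = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "checksums": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a study and write its files (FASTA/BED12/FASTQ/TSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    paths = {
        "reference": outdir / "reference.fasta",
        "annotation": outdir / "annotation.bed",
        "reads_1": outdir / "reads_1.fastq",
        "reads_2": outdir / "reads_2.fastq",
        "truth_table": outdir / "truth.tsv",
        "fusion_truth": outdir / "fusion_truth.json",
        "template": outdir / "template.fasta",
    }
    study.reference.to_fasta(paths["reference"])
    study.annotation.to_bed12(paths["annotation"])
    write_fastq(study.reads1, paths["reads_1"])
    write_fastq(study.reads2, paths["reads_2"])
    study.truth_table.to_csv(paths["truth_table"], sep="\t", index=False)
    ft = study.fusion_truth
    paths["fusion_truth"].write_text(
        json.dumps(
            {
                "five_prime_gene_id": ft.five_prime_gene_id,
                "three_prime_gene_id": ft.three_prime_gene_id,
                "genomic_breakpoint_5p": list(ft.genomic_breakpoint_5p),
                "genomic_breakpoint_3p": list(ft.genomic_breakpoint_3p),
                "junction_offset": ft.junction_offset,
                "junction_exons": list(ft.junction_exons),
                "derivative_chrom": ft.derivative_chrom,
            },
            indent=2,
        )
        + "\n"
    )
    write_templates([study.template], paths["template"])
    write_manifest(
        outdir / "manifest.json",
        config,
        paths,
        extra={"n_read_pairs": int(len(study.truth_table))},
    )
    paths["manifest"] = outdir / "manifest.json"
    return paths


def run_discover(
    config: PipelineConfig,
    fastq1: str | Path,
    fastq2: str | Path,
    reference: str | Path,
    annotation_path: str | Path,
    outdir: str | Path,
) -> DiscoveryResult:
    """File-level wrapper around :func:`discover`; writes the candidate table."""
    from .genome_model import load_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = GenomeAssembly.from_fasta(reference)
    annotation = load_annotation(annotation_path, "bed12")
    for gene in annotation:
        if gene.chrom not in genome:
            raise ValueError(
                f"annotation/reference mismatch: {gene.gene_id} on unknown {gene.chrom}"
            )
    reads1 = read_fastq(fastq1, 1)
    reads2 = read_fastq(fastq2, 2)
    result = discover(reads1, reads2, genome, annotation, config)
    result.table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    (outdir / "attrition.json").write_text(
        json.dumps(result.attrition, indent=2, sort_keys=True) + "\n"
    )
    write_manifest(
        outdir / "manifest.json",
        config,
        {
            "reads_1": Path(fastq1),
            "reads_2": Path(fastq2),
            "reference": Path(reference),
            "annotation": Path(annotation_path),
        },
        extra={"attrition": result.attrition},
    )
    return result
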