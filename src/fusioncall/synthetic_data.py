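"""Toy genomes, engineered fusion alleles, and paired-end read simulation.

Everything downstream of this module is exercised against data generated
here with a known truth table: a multi-chromosome toy genome carrying a
homologous decoy gene pair, an adjacent same-strand (read-through) pair
and an overlapping pair; derivative chromosomes joining two genes at
intronic breakpoints; and inward-facing paired-end reads with optional
substitution errors and clonal PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_model import Annotation, GeneModel, GenomeAssembly, revcomp, spliced_sequence
from .read_mapping import Read

_BASES = np.array(list("ACGT"))

# ids of the engineered decoys in the toy reference
READTHROUGH_PAIR = ("G1_1", "G1_2")
OVERLAP_HOST = "G2_2"
OVERLAP_NESTED = "G2_2_OV"
HOMOLOG_SOURCE = "G2_1"
HOMOLOG_COPY = "G2_1_HOM"


@dataclass(frozen=True)
class FusionTruth:
    """Ground truth for one engineered fusion allele."""

    five_prime_gene_id: str
    three_prime_gene_id: str
    genomic_breakpoint_5p: tuple[str, int]
    genomic_breakpoint_3p: tuple[str, int]
    junction_offset: int
    junction_exons: tuple[int, int]  # (last retained 5' exon, first retained 3' exon), 1-based
    derivative_chrom: str = ""


@dataclass
class ReadSimConfig:
    """Paired-end read simulation parameters.

    Defaults emulate an Illumina-style library: 75 nt paired reads from
    fragments of mean 300 bp (sd 50), constant Q35 base qualities.
    """

    read_length: int = 75
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    depth: int = 30  # fragments per transcript
    substitution_error_rate: float = 0.0
    clonal_duplicate_rate: float = 0.0
    quality_model: str = "constant"  # or "decay" (3' quality falloff to Q8)
    base_quality: int = 35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must be <= fragment_mean")
        for rate in (self.substitution_error_rate, self.clonal_duplicate_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.quality_model not in ("constant", "decay"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.take(_BASES, rng.integers(0, 4, size=n)))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently at the given rate."""
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_toy_reference(
    n_chrom: int = 3,
    genes_per_chrom: int = 3,
    exons_per_gene: tuple[int, int] = (2, 5),
    seed: int = 0,
    exon_len: tuple[int, int] = (150, 350),
    intron_len: tuple[int, int] = (200, 800),
    intergenic: tuple[int, int] = (300, 800),
) -> tuple[GenomeAssembly, Annotation]:
    """Build a deterministic toy genome with engineered decoy structures.

    Besides ``genes_per_chrom`` regular genes per chromosome, the
    reference always carries: an adjacent same-strand pair on chr1
    (read-through decoy), an overlapping pair on chr2 (single-exon gene
    nested in the first intron of its host), and a homologous copy of a
    chr2 gene (~2% divergence) planted on a different chromosome.
    """
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2 (inter-chromosomal events required)")
    if genes_per_chrom < 2:
        raise ValueError("genes_per_chrom must be >= 2")
    lo_ex, hi_ex = exons_per_gene
    if lo_ex < 2:
        raise ValueError("genes need at least 2 exons for intronic breakpoints")
    rng = np.random.default_rng(seed)

    chrom_seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        parts: list[str] = []
        pos = 0

        def emit(n: int) -> None:
            nonlocal pos
            parts.append(_rand_seq(rng, n))
            pos += n

        emit(int(rng.integers(*intergenic)))
        for g in range(1, genes_per_chrom + 1):
            gid = f"G{c}_{g}"
            if c == 1 and g <= 2:
                strand = "+"  # adjacent same-strand read-through decoy
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(lo_ex, hi_ex + 1))
            exons: list[tuple[int, int]] = []
            for e in range(n_ex):
                el = int(rng.integers(*exon_len))
                exons.append((pos, pos + el))
                emit(el)
                if e < n_ex - 1:
                    if c == 2 and g == 2 and e == 0:
                        il = 700  # wide intron 1 to host the nested overlap decoy
                    else:
                        il = int(rng.integers(*intron_len))
                    intron_start = pos
                    emit(il)
                    if c == 2 and g == 2 and e == 0:
                        ov_start = intron_start + 150
                        genes.append(
                            GeneModel(
                                gene_id=OVERLAP_NESTED,
                                chrom=chrom,
                                strand="+",
                                exons=((ov_start, ov_start + 320),),
                            )
                        )
            genes.append(
                GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=tuple(exons))
            )
            if c == 1 and g == 1:
                emit(int(rng.integers(150, 300)))  # short gap: read-through pair
            else:
                emit(int(rng.integers(*intergenic)))
        chrom_seqs[chrom] = "".join(parts)

    # homologous decoy: copy of one chr2 gene span, ~2% diverged, on another chromosome
    src = next(g for g in genes if g.gene_id == HOMOLOG_SOURCE)
    target_chrom = f"chr{n_chrom}" if n_chrom != 2 else "chr1"
    span_seq = chrom_seqs[src.chrom][src.start : src.end]
    mutated = _mutate(rng, span_seq, 0.02)
    spacer = _rand_seq(rng, 300)
    offset = len(chrom_seqs[target_chrom]) + len(spacer)
    chrom_seqs[target_chrom] = chrom_seqs[target_chrom] + spacer + mutated
    genes.append(
        GeneModel(
            gene_id=HOMOLOG_COPY,
            chrom=target_chrom,
            strand=src.strand,
            exons=tuple((s - src.start + offset, e - src.start + offset) for s, e in src.exons),
        )
    )
    return GenomeAssembly(chrom_seqs), Annotation(genes)


def engineer_fusion(
    genome: GenomeAssembly,
    annotation: Annotation,
    gene5: str,
    gene3: str,
    intron5_index: int,
    intron3_index: int,
    seed: int = 0,
    flank: int = 300,
) -> tuple[GenomeAssembly, GeneModel, FusionTruth]:
    """Create a derivative chromosome fusing two genes at intronic breakpoints.

    The breakpoints are drawn uniformly within the named transcription-order
    introns. The derivative chromosome carries the 5' gene in transcription
    orientation up to its breakpoint joined to the 3' gene from its
    breakpoint onward, and the returned fusion GeneModel splices the
    retained 5' exons to the retained 3' exons (mirroring the
    exon-1-to-exon-3 architecture of splicing-mediated fusion junctions).
    Breakpoint conventions: the 5' breakpoint is the last retained base,
    the 3' breakpoint the first retained base (0-based, original
    coordinates).
    """
    g5 = annotation[gene5]
    g3 = annotation[gene3]
    rng = np.random.default_rng(seed)
    i5s, i5e = g5.intron_tx(intron5_index)
    i3s, i3e = g3.intron_tx(intron3_index)
    bp5 = int(rng.integers(i5s, i5e))
    bp3 = int(rng.integers(i3s, i3e))

    chrom5 = genome[g5.chrom]
    chrom3 = genome[g3.chrom]
    if g5.strand == "+":
        a = max(0, g5.start - flank)
        five_part = chrom5[a : bp5 + 1]
        def map5(iv: tuple[int, int]) -> tuple[int, int]:
            return (iv[0] - a, iv[1] - a)
    else:
        e_lim = min(len(chrom5), g5.end + flank)
        five_part = revcomp(chrom5[bp5:e_lim])
        def map5(iv: tuple[int, int]) -> tuple[int, int]:
            return (e_lim - iv[1], e_lim - iv[0])
    l5 = len(five_part)
    if g3.strand == "+":
        three_part = chrom3[bp3 : min(len(chrom3), g3.end + flank)]
        def map3(iv: tuple[int, int]) -> tuple[int, int]:
            return (l5 + iv[0] - bp3, l5 + iv[1] - bp3)
    else:
        b = bp3 + 1
        three_part = revcomp(chrom3[max(0, g3.start - flank) : b])
        def map3(iv: tuple[int, int]) -> tuple[int, int]:
            return (l5 + b - iv[1], l5 + b - iv[0])

    retained5 = g5.exons_tx_order()[:intron5_index]
    retained3 = g3.exons_tx_order()[intron3_index:]
    fusion_exons = tuple(
        sorted([map5(iv) for iv in retained5] + [map3(iv) for iv in retained3])
    )
    junction_offset = sum(e - s for s, e in retained5)
    der_name = f"der_{gene5}_{gene3}"
    cds = g5.cds_start if (g5.cds_start is not None and g5.cds_start < junction_offset) else None
    fusion_model = GeneModel(
        gene_id=f"{gene5}-{gene3}",
        chrom=der_name,
        strand="+",
        exons=fusion_exons,
        cds_start=cds,
    )
    der_assembly = GenomeAssembly({**genome.sequences, der_name: five_part + three_part})
    # the fused transcript must start with the retained 5' exon prefix
    fused = spliced_sequence(der_assembly, fusion_model)
    prefix = spliced_sequence(genome, g5)[:junction_offset]
    if fused[:junction_offset] != prefix:
        raise AssertionError("engineered fusion violates its junction invariant")
    truth = FusionTruth(
        five_prime_gene_id=gene5,
        three_prime_gene_id=gene3,
        genomic_breakpoint_5p=(g5.chrom, bp5),
        genomic_breakpoint_3p=(g3.chrom, bp3),
        junction_offset=junction_offset,
        junction_exons=(intron5_index, intron3_index + 1),
        derivative_chrom=der_name,
    )
    return der_assembly, fusion_model, truth


def _qualities(cfg: ReadSimConfig, n: int) -> list[int]:
    if cfg.quality_model == "constant":
        return [cfg.base_quality] * n
    # linear 3' falloff down to Q8, exercising the Q15 trimming rule
    if n == 1:
        return [cfg.base_quality]
    return [
        int(round(cfg.base_quality - (cfg.base_quality - 8) * i / (n - 1)))
        for i in range(n)
    ]


def simulate_read_pairs(
    transcripts: Mapping[str, str], cfg: ReadSimConfig
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate inward-facing paired-end reads from a transcript set.

    Fragments are drawn per transcript at the configured depth with
    truncated-normal lengths; mate 1 is the forward 5' end of the
    fragment, mate 2 the reverse complement of its 3' end. A
    ``clonal_duplicate_rate`` fraction of fragments is re-emitted at
    identical coordinates under fresh read ids. The truth table maps
    every emitted read id to its source fragment; read ids themselves
    carry no semantics.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    reads1: list[Read] = []
    reads2: list[Read] = []
    rows: list[dict] = []
    counter = 0

    def emit(tid: str, seq: str, start: int, flen: int, duplicate_of: str) -> str:
        nonlocal counter
        rid = f"r{counter:07d}"
        counter += 1
        frag = seq[start : start + flen]
        m1 = _mutate(rng, frag[: cfg.read_length], cfg.substitution_error_rate)
        m2 = _mutate(
            rng, revcomp(frag)[: cfg.read_length], cfg.substitution_error_rate
        )
        reads1.append(Read(rid, 1, m1, _qualities(cfg, len(m1))))
        reads2.append(Read(rid, 2, m2, _qualities(cfg, len(m2))))
        rows.append(
            {
                "read_id": rid,
                "transcript": tid,
                "fragment_start": start,
                "fragment_end": start + flen,
                "duplicate_of": duplicate_of,
            }
        )
        return rid

    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        if len(seq) < cfg.fragment_mean:
            raise ValueError(
                f"transcript {tid!r} shorter than fragment_mean ({len(seq)} nt)"
            )
        for _ in range(cfg.depth):
            flen = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
            flen = max(cfg.read_length, min(len(seq), flen))
            start = int(rng.integers(0, len(seq) - flen + 1))
            rid = emit(tid, seq, start, flen, "")
            if rng.random() < cfg.clonal_duplicate_rate:
                emit(tid, seq, start, flen, rid)

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "transcript", "fragment_start", "fragment_end", "duplicate_of"],
    )
    return reads1, reads2, truth


def make_protein_matrix(
    n_proteins: int = 130,
    n_antibodies: int = 163,
    n_planted: int = 17,
    replicates: int = 4,
    effect: float = 5.0,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Two RPPA-style experiments with a planted concordant protein set.

    Emulates the paired comparisons of the cohort statistics stage: a
    patient-tissue contrast and a transfected-cell-line contrast over the
    same antibody panel (one protein may carry several antibodies).
    ``n_planted`` proteins are shifted by ``effect`` in the same direction
    in both experiments; the rest are null. Returns
    ``(experiment_a, experiment_b, planted_ids)`` where each experiment is
    a :class:`fusioncall.cohort_stats.ProteinMatrix`.
    """
    from .cohort_stats import ProteinMatrix

    if not (n_proteins <= n_antibodies <= 2 * n_proteins):
        raise ValueError("need n_proteins <= n_antibodies <= 2*n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(1, n_proteins + 1)]
    antibody_to_protein: dict[str, str] = {}
    for i, p in enumerate(proteins):
        antibody_to_protein[f"Ab{i + 1:03d}"] = p
    for j in range(n_antibodies - n_proteins):
        antibody_to_protein[f"Ab{n_proteins + j + 1:03d}"] = proteins[j]
    antibodies = sorted(antibody_to_protein)

    planted = sorted(rng.choice(proteins, size=n_planted, replace=False))
    directions = {p: (1.0 if rng.random() < 0.5 else -1.0) for p in planted}
    baseline = {p: float(rng.normal(10.0, 1.0)) for p in proteins}

    def build(case: str, control: str) -> ProteinMatrix:
        samples = [f"{case}_{r + 1}" for r in range(replicates)] + [
            f"{control}_{r + 1}" for r in range(replicates)
        ]
        conditions = pd.Series(
            [case] * replicates + [control] * replicates, index=samples
        )
        data = np.empty((len(antibodies), len(samples)))
        for i, ab in enumerate(antibodies):
            p = antibody_to_protein[ab]
            shift = directions.get(p, 0.0) * effect
            case_vals = rng.normal(baseline[p] + shift, noise_sd, replicates)
            ctrl_vals = rng.normal(baseline[p], noise_sd, replicates)
            data[i] = np.concatenate([case_vals, ctrl_vals])
        values = pd.DataFrame(data, index=antibodies, columns=samples)
        return ProteinMatrix(values, conditions, dict(antibody_to_protein))

    return build("S5", "S19"), build("shortWDFY2", "wtWDFY2"), list(planted)
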