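# Methods

This note describes the computation `fusioncall` performs, the defaults
it ships with and why, what the synthetic studies emulate, and the
numerical/design choices made where the problem left room.

## Discovery model

A fusion transcript is detected from paired-end RNA-seq as a set of
*chimeric read pairs*: fragments whose two mates map uniquely to two
different, non-overlapping genes. Reads are quality-trimmed 5'→3' at the
first base below Q15 and discarded below 45 bp. Mapping is two-tiered:
mates are first placed on the spliced transcriptome; pairs with at most
one transcriptome placement send their unplaced mates to the genome.
Chimeric evidence requires 0 mismatches in the transcriptome tier and
tolerates 2 in the genome tier (the transcriptome-tier rule is the
defining one; the genome tier's tolerance is a surfaced parameter).
Evidence from both tiers is pooled per unordered gene pair.

A pair-classification subtlety: a mate placed in a second gene but above
its tier's chimera mismatch tolerance is treated as not confidently
mapped and the pair classed `one_end_mapped`. With the shipped defaults
(tier-1 mapping tolerance = tier-1 chimera tolerance = 0) the situation
cannot arise; it matters only if the tiers are reconfigured.

### Filter cascade

Candidates must survive, in canonical order (each filter is a pure
predicate, so pass/fail is order-insensitive; only the recorded first
failure depends on order):

1. **Clonal dedup** — supporting pairs whose two mate start positions
   are both within 5 bp of an already retained pair are collapsed
   (lowest read id kept; the survivor's identity is biologically
   irrelevant). "Both mates within 5 bp" is the duplicate definition;
   a pair differing by ≥5 bp in either mate is independent evidence.
2. **Support floor** — ≥2 surviving pairs.
3. **Strand predominance** — two genes can fuse in four strand
   combinations; a real fusion produces one. The modal combination must
   reach a fraction of 0.8 (tie ⇒ fail). The threshold operationalizes
   "predominantly"; it is a config parameter, not a measured constant.
4. **Overlap exclusion** — gene pairs with intersecting genomic spans
   are never called (their "chimeras" are annotation artifacts).
5. **Homology exclusion** — gene pairs whose spliced transcripts share
   ≥5% of 31-mers (normalized by the smaller k-mer set, N-containing
   k-mers excluded) are treated as homologous and excluded. The k-mer
   criterion is this package's operationalization of a
   shared-sequence filter; alignment-based homology is deliberately out
   of scope. Transcripts shorter than k are not assessable and are not
   excluded on homology grounds.
6. **Remap validation** — every surviving supporting read is rescanned
   against the full reference set (transcripts + genome) by exhaustive
   Hamming scan; any equal-or-better placement outside the read's own
   gene locus rejects the candidate. The scan is its own oracle.

Gene pairs are classified `interchromosomal`, `overlapping`,
`neighbor_readthrough` (same chromosome, gap ≤ 100 kb) or
`long_intrachromosomal`. The neighbor gap has no principled published
value; 100 kb is a conventional read-through scale and is configurable.
Read-through candidates may pass the cascade — they are genuine
chimeric transcripts — but are typed as read-through so downstream
fusion-gene analysis can set them aside.

Across a cohort, passing candidates are prioritized when they recur in
≥2 samples, or reach ≥3 surviving pairs in one sample, or involve a
gene from a user-supplied cancer-gene catalog (a plain id list; no
catalog is bundled).

### Junction support

Junction templates are validated junction sequences (in practice
Sanger-sequenced amplicons; in the synthetic studies, the engineered
fusion transcript) carrying the 0-based offset of the first base 3' of
the junction. Only reads the two-tier mapper left unplaced are
considered. A read counts iff: its mate maps to a parental gene; its
best template placement (exhaustive Hamming scan, both strands; a tied
best placement rejects as ambiguous) spans the junction with ≥6 aligned
bases per side; total mismatches ≤2 with zero inside the ±6 nt window.
"Six nucleotides on either side" is read as ≥6 aligned
(matched-or-mismatched) bases per side with the zero-mismatch constraint
applied to exactly those positions. Combined support is reported as
`chimeric+junction`.

Pair evidence alone cannot order the partners (the four strand
combinations are symmetric); orientation is assigned from the template,
and a palindromic template is rejected for manual resolution.

## Annotation model

For a fusion transcript with junction offset *j*:

- **Readthrough ORF** — translated from the 5' partner's native ATG
  (which must lie upstream of *j*) to the first in-frame stop. Residues
  whose codon touches *j* or anything 3' of it count as *novel*. When
  the 3' partner's native frame is known, the prediction is flagged
  in-frame/out-of-frame; out-of-frame readthrough yields the classic
  truncated 5' protein plus a short novel tail.
- **Internal-start ORF** — the first ATG at/after *j* that is in frame
  with the 3' partner's native stop codon, translated to the first stop
  in that frame. This is the N-terminally truncated 3'-partner isoform.
  The rule is positional only (no Kozak-context scoring); when no such
  ATG exists the product is reported absent. The predictor reports both
  ORFs and never ranks them by translatability — which ORF a ribosome
  actually selects is cell biology outside this model.
- **Masses** — average (not monoisotopic) residue masses + one water,
  reported in kDa with two decimals and an integer-rounded figure,
  matching the granularity such products are quoted at.
- **Breakpoint offsets** — transcription-direction distances from the
  last retained 5' exon end to the 5' breakpoint and from the 3'
  breakpoint to the first retained 3' exon start, strand-aware. A
  breakpoint at the exon's terminal base gives 0; one strictly inside an
  exon is an error (splicing-compatible breakpoints are intronic).
- **Microhomology** — the longest run of identical sequence immediately
  5' (or symmetrically 3') of both partners' junction points, probed to
  15 nt by default; length 0 is the non-homologous end joining
  signature.

## Cohort statistics

- **Recurrence** — per fusion and sample group: positives, totals,
  percent (integer-rounded, one-decimal secondary column); empty groups
  report NA.
- **Exact Mann-Whitney-Wilcoxon** — for ≤12 total observations the null
  distribution of U (mid-ranks under ties) is enumerated over all
  C(n+m, n) labelings; two-sided p = 2·min(lower tail, upper tail),
  capped at 1. Beyond 12, a normal approximation with tie and continuity
  correction is used. The cutoff of 12 keeps enumeration ≤ C(12,6)=924
  labelings — exact where exactness matters (replicate-scale groups),
  cheap elsewhere. Triplicate groups cannot reach p<0.1 exactly; the
  function warns when a p<0.05 screen is unattainable rather than
  silently approximating.
- **Differential screen** — antibody-level tests collapse to protein
  level by minimum p (direction from that antibody). No
  multiple-testing correction is applied by default — the screen is an
  uncorrected p<0.05 one; a Benjamini-Hochberg helper exists for callers
  who want it.
- **Concordance** — proteins significant in both of two comparisons with
  equal direction, deterministically ordered.
- **Hypergeometric enrichment** — upper-tail P(X≥k) via log-stable
  survival-function evaluation, validated against draw enumeration.
  `enrichment_inversions` enumerates all (pathway size, hit count) pairs
  consistent with a printed p-value when the underlying counts are not
  reported — an exploration utility, not an estimator.

## Synthetic studies

`make_toy_reference` builds 3 chromosomes × 3 genes (2–5 exons of
150–350 bp, introns 200–800 bp) plus three engineered decoys: an
adjacent same-strand pair on chr1 (read-through), a single-exon gene
nested in a chr2 intron (overlap), and a ~2% diverged full-span copy of
a chr2 gene on another chromosome (homology). `engineer_fusion` draws
intronic breakpoints uniformly within named introns and emits a
derivative chromosome plus the spliced fusion model and a truth record
(breakpoints, junction offset, junction exons).

`simulate_read_pairs` draws per-transcript fragments
(truncated-normal length, mean 300 / sd 50, within a 200–500 bp
library-size regime), emits inward-facing 75 nt mates (Illumina-style
chemistry), injects independent substitution errors, and re-emits a
configurable fraction of fragments at identical coordinates as clonal
duplicates under fresh read ids. Qualities are constant Q35 or an
optional linear 3' decay to Q8 that exercises the Q15 trimming rule.
Read ids carry no semantics; all truth lives in the sidecar table. The
standard study simulates reads from every parental transcript, the
fusion transcript, and three artifact chimera transcripts that feed the
decoy filters with real evidence. Default depth is 30 fragments per
transcript — enough that ≥2 independent junction-region fragments
essentially always exist at these transcript lengths.

What the simulations do **not** model: indels, PCR chimeras other than
exact clonal duplicates, expression variation beyond uniform depth,
position-dependent error profiles, and intron-containing
(pre-mRNA/DNA) reads. Passing the end-to-end tests therefore
demonstrates the correctness of the filtering/counting logic under its
own assumptions, not performance on real libraries.

The protein-matrix generator plants 17 same-direction shifted proteins
among 130 (163 antibodies, some proteins with two) across two paired
comparisons, with 4 replicates per condition. Four replicates is the
smallest design where the exact two-sided test can cross 0.05 (minimum
p = 2/70 ≈ 0.029); triplicates cannot. Because the screen is
uncorrected, a null protein passes both comparisons in the same
direction with probability ≈ 4×10⁻⁴ — across 113 nulls an occasional
false concordant (~1 study in 20) is expected behavior of the screen,
not a defect.

## Numerical and engineering choices

- Internal coordinates are 0-based half-open; user-facing positions are
  rendered 1-based (genome-browser convention) only at the report layer.
- The mapper seeds with `max_mismatches+1` disjoint 16-mer segments; by
  pigeonhole, any placement within tolerance has at least one exact
  seed, so seed-and-extend equals the brute-force Hamming scan
  exactly. Reads too short to carry that many seed segments fall back to
  the brute-force scan. Ties are all reported in (reference, position,
  strand) order; `is_unique` is true only for a single best placement,
  and non-unique reads are treated as unmapped by the pipeline
  (uniquely-mappable requirement).
- The junction truth identity used in tests counts straddlers among the
  reads the mapper left unplaced: a read straddling with a minimal
  (6–8 nt) flank occasionally matches genomic context within the genome
  tier's 2-mismatch tolerance and is legitimately consumed upstream —
  the junction criterion applies to previously unmappable reads by
  definition.
- SAM ingestion requires the NM tag (mismatch counts are load-bearing);
  records without it are rejected rather than guessed.
- Dedup start positions are genomic where available and
  transcript-relative otherwise, flagged per record; the 5 bp rule is
  applied to whichever pair of coordinates the evidence carries.
- Determinism: every stochastic component takes an explicit seed;
  identical seeds give byte-identical FASTQ and reports, and run
  manifests record config snapshots and input checksums.

## Problem sizes

The shipped defaults run the full synthetic study (15 transcripts,
~450 read pairs, ~40 kb of reference) in a few seconds; the oracle
equivalence checks use a 30 kb reference with 1000 reads and full
enumeration grids up to C(20,8) subsets. These sizes were chosen to make
every oracle exhaustive while keeping the whole suite interactive.

## Known limitations

- The homology filter's 5%-of-31-mers threshold is an operational
  stand-in; no published threshold exists for the shared-sequence
  exclusion it implements.
- De novo junction discovery (from soft-clipped reads or assembly) is a
  non-goal: templates come from validated junctions.
- The mapper is ungapped by design; spliced or indel-bearing placements
  are out of scope (junction reads are handled by the template stage,
  not the aligner).
- Patient-scale quantities (hundreds of putative fusions from hundreds
  of millions of reads) depend on data that cannot be regenerated
  synthetically; the pipeline reproduces the computation, not those
  counts.
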