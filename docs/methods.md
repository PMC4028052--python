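# Methods

`txqc` automates the quality-control and repair steps that turn a raw
transcript collection — assembled de novo, from genome-guided alignment, or
from EST clustering — into a defensible transcriptome. It is aimed at
non-model organisms whose genomes break default tool assumptions; the
motivating case is a GC-rich (~65%) haptophyte genome in which the dominant
splice donor is the non-canonical GC (GC-AG introns) and intron retention is
pervasive. This note describes each procedure, its assumptions and tunable
parameters, the numerical choices made where the design was genuinely open,
and what the synthetic fixtures do and do not demonstrate.

## Coordinates and I/O

All internal coordinates are 0-based half-open. Conversion happens only at
file boundaries: GTF and fixedStep wiggle are 1-based (inclusive for GTF),
BED and bedGraph pass through unchanged. A transcript model is an ordered
list of non-overlapping exon intervals with strand `+`, `-` or `?`
(unknown); gaps between consecutive exons are its introns, and models with
an intron shorter than the configured minimum (default 30 bp, matching the
spliced-aligner setting used to produce such models) can be rejected at
read time. Coverage is a dense per-base depth vector per chromosome;
positions absent from the input file have depth 0, and overlapping bedGraph
records are an error rather than being summed, because silent summation
hides double-counted input.

## ORF extraction

Fragment-heavy collections rarely include complete 5' ends, so the default
ORF definition is **stop-to-stop**: a maximal codon run bounded by stop
codons, with sequence ends acting as boundaries and no initial methionine
required. Met-to-stop is available as an alternative mode; each Met-to-stop
ORF is the suffix of a stop-to-stop ORF beginning at its first methionine.
All six frames of both strands are scanned, because fused transcripts carry
genes on opposite strands.

Conventions, chosen for determinism and robustness to draft genomes:

* The reported interval (on forward transcript coordinates) includes the
  terminal stop codon when one is present; the peptide never includes it.
  Length thresholds downstream refer to peptide length.
* Codons containing N translate to X and X never terminates an ORF, so
  assembly holes do not shatter reading frames. `TAN` is treated as X even
  though it could resolve to a stop.
* Ordering: peptide length descending, then `+` strand before `-`, then
  smaller start. `longest_orf` is the head of that ordering. Note that with
  both strands scanned, a reverse-strand run can outrank a "visually
  obvious" forward ORF (e.g. in `ATGAAATAG` the reverse-strand read
  `CTATTTCAT` holds a stop-free 3-residue run that outranks `MK`).

## Fused-transcript splitting

Assemblers join overlapping transcribed units into single contigs; in
genomes with compact gene spacing this typically happens where 3'UTRs of
opposite-strand gene pairs overlap. The splitter works purely from ORF
geometry, in this order (defaults in parentheses):

1. longest-ORF coverage < `remove_cov` (0.10) → **remove**;
2. coverage ≥ `keep_cov` (0.80) → **keep**;
3. length < `min_parent_len` (2000 bp) → **keep** (2000 bp exactly is
   splittable — the gate is "shorter than");
4. among the top `max_orfs` (3) ORFs with peptides ≥ `min_peptide_aa`
   (100 aa), the largest set (3, then 2) of pairwise non-overlapping ORFs
   whose induced children are all ≥ `min_child_len` (300 bp) triggers a
   **split**; otherwise **keep**.

The removal rule is applied first, unconditionally, so junk transcripts do
not survive on a length technicality. Both the 300 bp child floor and the
100 aa peptide floor are enforced (they coincide only when the child is all
coding, so the intersection is the conservative choice). Non-overlap is
evaluated on forward-projected intervals regardless of strand — physical
ownership of sequence is what makes a split well-formed. Cuts are placed at
the midpoint of the gap between consecutive participating ORFs, keeping the
UTR-overlap evidence inspectable in both children. When several pairs
qualify, the pair with the highest total peptide length wins (ties: leftmost
ORF start). Splitting is idempotent on its own output for the fixtures used
here; monotonicity (raising the peptide floor never increases splits) is
asserted as a property test.

## Presence QC against a curated reference set

A small set of manually curated genes is searched in each collection with a
local aligner. The hit score is

    score = matches − mismatches − (gap openings in query) − (gap openings in target)

with no gap-length term, and a gene is *found* at the DNA level when its
best hit reaches `min_score` (default 200).

**A degeneracy of this scoring, and its consequences.** With free gap
extension, an exhaustive local aligner can chain short chance matches across
unrelated sequences at a cost of one point per jump; empirically the optimal
score between two unrelated random DNA sequences of length n (GC 0.65) grows
as ≈ 0.37·n. Seeded aligners do not surface such chains, exhaustive DP does.
Three design choices follow:

* The engine is exact DP (biopython's `PairwiseAligner`, match +1,
  mismatch −1, open −1, extend 0), verified in tests against an independent
  Gotoh implementation. Its tie-break (first traceback) is deterministic.
* `identity` is defined as matches over **all** alignment columns, gap
  columns included. Chance chains carry long gaps and score low identity
  (~0.3); genuine near-exact matches stay near 1. Span-based identity would
  be meaningless under this scoring.
* A score threshold discriminates presence only while the chance score of
  the longest unrelated pair stays below it; at threshold 200 that bounds
  useful reference genes to roughly ≤ 500 bp. The presence *fixture*
  therefore uses designed genes of 300–450 bp (intact copies score ≥ 300,
  chance pairs ≤ ~170). On real data with kb-scale references, a seeded
  aligner's score-200 cutoff behaves differently from exhaustive DP; the
  threshold and the criterion below are both configurable for that reason.

The protein level exists because frameshifts and wrong-frame translations
lose genes that are intact at the DNA level. Collections are compared as
longest-ORF peptides; a reference peptide is *found* when some hit covers
≥ `min_coverage` (0.80) of it at ≥ `min_identity` (0.95). Terminal
truncations pass; a mid-ORF frameshift caps achievable coverage near 50% and
fails. An optional per-collection eligibility mask marks genes without
input support (e.g. too few reads) as `no_input_support` so they can be
excluded from denominators. The membership matrix (genes × collections of
found flags) is Venn-ready.

`characterize_collection` profiles a collection: length histogram (default
bin edges 500/1000), longest-ORF coverage histogram (ten equal bins over
[0,1]), and medians of length, ORF length and ORF coverage.

## Splice-junction landscape

Junctions are taken from transcript models against the genome: donor = first
two intronic bases in transcription direction, acceptor = last two; on the
`-` strand both are reverse-complemented from forward genome sequence.
Deduplication is on (chromosome, intron interval, strand), so alternate
isoforms sharing an intron count once. Donors are binned to
{GC, GT, GA, AT, CT, other} and acceptors to {AG, AC, GC, AT, other}; any
dinucleotide containing N is `other`. Percentages are reported rounded to
integers. Strand-unknown models (typical of EST alignments) are oriented by
majority vote of their acceptors (`AG` read forward vs `CT` at the intron
start, i.e. AG read reverse); ties fall back to `+` for extraction but are
reported as `?` by `infer_strand_by_acceptor`. A separate filter keeps only
AG-acceptor junctions — the appropriate noise filter for EST-derived
alignments, where non-AG acceptors are dominated by misalignment.

## Unexplained regions and intron retention

`find_unexplained_regions` reports maximal runs where every base has depth
≥ `min_cov` (default 50), no base overlaps an excluded interval, and length
≥ `min_length` (default 300 bp). "Minimum coverage" is interpreted as
per-base depth (the floor pairs naturally with a per-region length floor);
a `mean-depth` mode is exposed for sensitivity analysis (maximal non-zero
runs whose mean reaches the floor). Exclusions default to full model spans —
a deep run inside an annotated intron is explained by its transcript — with
an exon-only mode available. An exclusion splits a run; each side is tested
against the length floor independently. Regions are strandless because
coverage is unstranded.

Intron retention is called per intron: *retained* iff every base reaches
`depth_floor` (default 1 — the criterion is presence of reads throughout,
not a depth cutoff; the floor is configurable because library depth varies).
The covered fraction is reported alongside the binary call to support
threshold sensitivity analysis. Exon skipping and alternate donor/acceptor
detection are out of scope: they need junction-spanning read evidence, and
coverage tracks are this toolkit's ingestion boundary.

## Redundancy removal and merging

`dedupe` is greedy longest-first clustering (ties: lexicographically
smallest id): each sequence joins the first representative it matches at
≥ `identity_threshold` over ≥ 80% of its own length, else founds a cluster;
only representatives are emitted. The contract is the output property — no
residual pair of representatives matches at the operating threshold — not
internal equivalence with any particular clustering program. At protein
level, comparisons run on longest-ORF peptides while the emitted records
remain the original transcripts.

`merge_collections` reconciles an aggressive clustering (longer transcripts,
genes lost) with a conservative one (nothing lost, redundancy kept): each
secondary transcript is *identical* (reciprocal ≥ `identity`, default 0.98,
over ≥ `containment_cov`, default 0.95, of both lengths), *contained* (the
same over its own length within a primary transcript), or *kept*.
Identical/contained transcripts are replaced by their best-scoring primary
counterpart (ties: smallest primary id), each emitted once; kept transcripts
pass through unchanged. Transcripts under 301 bp are dropped from both
collections before matching, so the conservation identity
`final_total = primary_used + secondary_kept` holds exactly and is asserted
in tests. The near-exact default thresholds encode the assumption that both
collections derive from the same underlying reads.

## Synthetic fixtures

The generator (`txqc.synth`) produces, deterministically per `SynthSpec`
(identical spec ⇒ byte-identical files):

* a genome of i.i.d. bases at the target GC (default 0.65, length 500 kb);
* non-overlapping multi-exon gene loci (default 100 genes, 1–17 exons,
  transcripts 569–4661 bp, introns 30–200 bp). Donor dinucleotides are
  **written into the genome** with exact largest-remainder counts from the
  mix (default 0.56/0.40/0.04 GC/GT/GA; acceptors all AG), so junction-mix
  recovery is exact rather than statistical;
* planted ORFs: runs of non-stop codons flanked by seeded stop codons.
  UTR/intergenic/decoy filler is random sequence stamped every ≤ 21 bp with
  `TTAATTAATTAA`, which contains a stop codon in all six frames at any
  phase; fillers are unique per transcript so they never cross-align. Every
  planted transcript is verified (rejection sampling under the seeded
  generator) to carry its planted ORF as the unique longest;
* fusions: two designed transcripts joined 3'-to-3' with a 20–100 bp
  overlap, second side reverse-complemented (opposite strands) by default,
  each side ≥ 100 aa, parent ≥ 2000 bp, longest-ORF coverage inside
  (10%, 80%); a same-strand mode covers the other fusion class;
* coverage: exons at the spec depth (default 60×); a retention-rate
  fraction of introns (rounded count, default 0.89) covered end-to-end at
  depths 1–5, every other intron holding a zero-depth gap; and (default) 5
  intergenic islands of 400 bp at 60× flanked by zero coverage;
* a gold fixture: 20 designed reference genes of 300–450 bp plus a
  collection with 17 intact copies, 2 single-base-insertion frameshifts and
  1 gene absent.

What the fixtures emulate: the donor-mix skew, opposite-strand 3'UTR
fusions, pervasive intron retention, deep unannotated coverage islands, and
the DNA-found/protein-lost gap caused by frameshifts. What they do not:
read-level noise, expression variation, repeat-induced misassembly, spliced
misalignment artifacts, paralogy, or chance homology between genes —
planting is adversarially clean so that recovery can be asserted exactly.
Passing the fixture suite therefore demonstrates correctness of the decision
logic, not performance on noisy real data.

## Problem sizes and numerical choices

The standard verification runs use: 500 kb genome / 100 six-exon genes (500
introns) for junction-mix recovery; 10 fusions + 20 intact + 5 decoys for
the splitter; 1000 random sequences of 100–2000 nt against a brute-force
six-frame scanner; 200 pairs ≤ 300 nt with planted homology against an
independent Gotoh DP; 50 three-exon genes (100 introns) for retention; 100
random coverage vectors plus 5 planted islands for the region finder. All
random draws come from seeded NumPy generators; the fixture generator uses
per-operation child seeds (`default_rng([seed, stream])`) so operations are
order-independent.

## Known limitations

* The alignment scoring degeneracy above: score thresholds lose meaning on
  kb-scale unrelated sequences under exhaustive DP. Use the protein
  coverage/identity criterion, or shorter references, where this bites.
* `dedupe` is O(n·m) alignments with no k-mer prescreen; it is meant for
  collection-scale spot checks and fixtures, not for millions of reads.
* Junction extraction trusts the models' intron coordinates; it does not
  attempt to detect or correct aligner-induced junction misplacement.
* Retention calls cannot distinguish genuine retention from pre-mRNA
  contamination; that is a wet-lab question.
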