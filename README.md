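# txqc — transcriptome QC and refinement toolkit

Automated transcript collections — de novo assemblies, genome-guided models,
clustered ESTs — routinely carry silent defects: artificially fused
transcripts where neighbouring genes' 3'UTRs overlap, genes present at the
DNA level but lost in translation to frameshifts or wrong-frame ORFs,
redundant near-duplicates, and transcribed regions no tool ever modelled.
In non-model organisms these problems are amplified by genome properties
that break default tool assumptions — the motivating case is a GC-rich
(~65%) algal genome whose dominant splice donor is the non-canonical **GC**
(GC-AG introns) and whose introns are pervasively retained in reads.

`txqc` provides the decision logic to detect and repair these defects, plus
a deterministic synthetic-fixture generator so every operation is testable
with planted truth and no downloads:

| module | what it does |
|---|---|
| `txqc.seqio` | FASTA/GTF/BED/bedGraph/wiggle I/O, one internal coordinate convention (0-based half-open) |
| `txqc.orf` | six-frame ORF enumeration, **stop-to-stop** by default (no Met required; ends act as boundaries) |
| `txqc.splitter` | fused-transcript detection/splitting from the geometry of the top three ORFs |
| `txqc.qc` | local-alignment presence checks of curated reference genes (DNA and protein level), collection length/ORF profiles |
| `txqc.junctions` | splice-junction extraction, coordinate-level deduplication, donor/acceptor tallies, AG-acceptor filter, strand inference |
| `txqc.regions` | deeply covered intervals outside known models (min depth 50, min length 300 by default) |
| `txqc.retention` | intron-retention calls from per-base coverage (reads throughout the intron) |
| `txqc.cluster` | greedy identity dedupe; identical-or-contained merging of two clusterings |
| `txqc.synth` | planted-truth fixture bundles (genome, GTF, transcripts, fusions, coverage, reference sets) |

The splitter's rules, in order: transcripts whose longest stop-to-stop ORF
covers < 10% of the sequence are removed; ≥ 80% are kept; shorter than
2000 bp are kept; otherwise, if two or three of the top ORFs (peptides
≥ 100 aa) occupy non-overlapping intervals and every resulting child is
≥ 300 bp, the transcript is split between them. A split across strands is
flagged — the signature of the opposite-strand 3'UTR-overlap fusion.

The presence hit score is `matches − mismatches − gap_openings` with a
default threshold of 200; protein-level "found" is coverage ≥ 80% of the
reference peptide at identity ≥ 95%, which catches frameshift losses while
tolerating terminal truncation. See `docs/methods.md` for the scoring
caveats that come with exhaustive alignment under this scheme, and for
every default's rationale.

## Worked example

Generate a small fixture genome (20 genes, planted donor mix
0.56/0.40/0.04 GC/GT/GA, all-AG acceptors, 89% intron retention), then run
the junction, splitter and retention analyses:

```python
from txqc import synth, junctions, splitter, retention

spec = synth.SynthSpec(seed=42, genome_length=120_000, n_genes=20,
                       exons_per_gene=(1, 8), n_fusions=3)
genome = synth.generate_genome(spec)
models, transcripts, truth = synth.generate_genes(spec, genome)

tally = junctions.classify(
    junctions.extract_junctions(models, {genome.name: genome}))
print("introns:", tally.total)
print("donor %:", tally.donor_percentages())
print("acceptor %:", tally.acceptor_percentages())

fused, _ = synth.generate_fusions(spec)
intact = synth.generate_intact(spec, 5)
decoys = synth.generate_decoys(spec, 2)
out, report = splitter.split_collection(fused + intact + decoys)
print("split report:", report)

track, cov_truth = synth.generate_coverage(spec, models, genome)
calls, summary = retention.assess_retention(
    [(genome.name, r["start"], r["end"], "+") for r in cov_truth["retention"]],
    track)
print("retention:", summary.retained, "/", summary.total, f"({summary.fraction:.0%})")
```

prints

```
introns: 70
donor %: {'GC': 56, 'GT': 40, 'GA': 4, 'AT': 0, 'CT': 0, 'other': 0}
acceptor %: {'AG': 100, 'AC': 0, 'GC': 0, 'AT': 0, 'other': 0}
split report: {'keep': 5, 'split2': 3, 'split3': 0, 'removed': 2, 'opposite_strand': 3}
retention: 62 / 70 (89%)
```

The 20 genes carry 70 introns whose planted donor mix is recovered exactly
(56% GC / 40% GT / 4% GA, acceptors all AG). The three planted
opposite-strand fusions are each split in two (children named
`fusion000.1`, `fusion000.2`, ...), the five intact controls pass through,
the two low-ORF decoys are removed, and 62 of 70 introns (89%, the planted
rate) show coverage throughout their length.

The same operations are available from the shell:

```
txqc synth --seed 42 --genome-length 120000 --genes 20 --fusions 3 -o fixtures/
txqc junctions --gtf fixtures/models.gtf --genome fixtures/genome.fasta -o tally.json
txqc split fixtures/fused.fasta -o split.fasta --report report.json
txqc retention --gtf fixtures/models.gtf --genome fixtures/genome.fasta \
    --coverage fixtures/coverage.bedgraph -o retention.tsv
```

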