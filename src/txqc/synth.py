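"""Deterministic synthetic fixtures: a GC-rich toy genome with planted truth.

The generator emulates the situations this toolkit exists for: a GC-rich
(default 65%) genome carrying multi-exon genes whose splice donors follow a
planted mix dominated by non-canonical GC (default 56% GC / 40% GT / 4% GA,
acceptors all AG), transcripts fused through opposite-strand 3'UTR overlaps,
per-base coverage tracks with a planted intron-retention rate, and deep
coverage islands outside every model ("unexplained" regions).

Planting is by construction, not by sampling: donor dinucleotides are
written into the genome (exact counts via largest-remainder apportionment),
ORFs are codon runs free of in-frame stops flanked by seeded stop codons,
and UTR/intergenic filler is built from a block that contains stop codons in
all six frames, so no spurious long ORF can arise. Every generated
transcript is verified to have its planted ORF as the unique longest one.
Identical SynthSpec values give byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import orf as orf_mod
from .orf import revcomp
from .seqio import (
    CoverageTrack,
    GenomeSequence,
    TranscriptModel,
    write_bedgraph,
    write_fasta,
    write_gtf,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NON_STOP_CODONS = sorted(
    set(orf_mod._CODON_TO_AA) - set(orf_mod._STOP_CODONS)
)

CHROM = "synth1"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic fixture bundle."""

    seed: int = 42
    genome_length: int = 500_000
    gc_content: float = 0.65
    n_genes: int = 100
    exons_per_gene: Tuple[int, int] = (1, 17)
    transcript_length_range: Tuple[int, int] = (569, 4661)
    donor_mix: Tuple[Tuple[str, float], ...] = (("GC", 0.56), ("GT", 0.40), ("GA", 0.04))
    min_intron: int = 30
    intron_length_range: Tuple[int, int] = (30, 200)
    n_fusions: int = 10
    fusion_overlap_range: Tuple[int, int] = (20, 100)
    retention_rate: float = 0.89
    read_depth: int = 60
    n_unexplained: int = 5
    unexplained_length: int = 400
    unexplained_depth: int = 60

    def __post_init__(self):
        total = sum(w for _, w in self.donor_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("donor_mix must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# Filler and planted-ORF building blocks
# ---------------------------------------------------------------------------

#: Contains a stop codon in every one of the six reading frames at any phase
#: (it is its own reverse complement modulo the TTAA period), so stamping it
#: periodically bounds every stop-free run regardless of frame and strand.
_STOP_STAMP = "TTAATTAATTAA"


def _filler(rng: np.random.Generator, n: int) -> str:
    """Stop-dense filler: random chunks interleaved with stop stamps.

    Unique per call (random chunks), so fillers of different transcripts do
    not align; the stamps bound every stop-free run to well under 20 codons
    in all six frames.
    """
    if n <= 0:
        return ""
    parts = []
    ln = 0
    while ln < n:
        k = int(rng.integers(6, 22))
        chunk = _BASES[rng.integers(0, 4, size=k)].tobytes().decode("ascii")
        parts.append(chunk)
        parts.append(_STOP_STAMP)
        ln += k + len(_STOP_STAMP)
    return "".join(parts)[:n]


def _random_peptide_codons(rng: np.random.Generator, n_aa: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_aa)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


@dataclass(frozen=True)
class PlantedTranscript:
    sequence: str
    orf_start: int  # interval as the ORF finder reports it (incl. trailing stop)
    orf_end: int
    peptide: str

    @property
    def pad3(self) -> int:
        return len(self.sequence) - self.orf_end

    @property
    def pad5(self) -> int:
        return self.orf_start - 3  # leading seeded stop codon


def make_transcript(rng: np.random.Generator, total_len: int, orf_aa: int,
                    max_other_aa: Optional[int] = None,
                    pad5: Optional[int] = None,
                    max_tries: int = 80) -> PlantedTranscript:
    """A transcript with a planted, verified unique-longest + strand ORF.

    Layout: [filler][TAA][orf_aa non-stop codons][TAA][filler]. The planted
    ORF is verified to be the unique longest ORF in all six frames, and —
    when ``max_other_aa`` is given — every other ORF is at most that long.
    """
    core = 3 * orf_aa + 6
    if total_len < core:
        raise ValueError(f"transcript of {total_len} nt cannot hold a {orf_aa} aa ORF")
    limit = max_other_aa if max_other_aa is not None else orf_aa - 1
    for _ in range(max_tries):
        p5 = int(rng.integers(0, total_len - core + 1)) if pad5 is None else pad5
        seq = (
            _filler(rng, p5)
            + "TAA"
            + _random_peptide_codons(rng, orf_aa)
            + "TAA"
            + _filler(rng, total_len - core - p5)
        )
        assert len(seq) == total_len
        found = orf_mod.find_orfs(seq, min_aa=1)
        top = found[0]
        expected = (p5 + 3, p5 + 3 + 3 * orf_aa + 3)
        if (
            top.strand == "+"
            and (top.start, top.end) == expected
            and top.aa_len == orf_aa
            and all(o.aa_len <= limit for o in found[1:])
        ):
            return PlantedTranscript(seq, expected[0], expected[1], top.peptide)
    raise RuntimeError("could not plant a unique-longest ORF; spec infeasible")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(spec: SynthSpec) -> GenomeSequence:
    """I.i.d. bases with P(G)+P(C) = gc_content, split evenly."""
    if spec.genome_length < 10 * spec.transcript_length_range[1]:
        raise ValueError("genome_length must be >= 10x the longest transcript")
    rng = spec.rng(0)
    gc = spec.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=spec.genome_length, p=p)
    seq = _BASES[idx].tobytes().decode("ascii")
    return GenomeSequence(CHROM, seq)


# ---------------------------------------------------------------------------
# Genes with a planted junction mix
# ---------------------------------------------------------------------------

def _apportion(weights: Sequence[Tuple[str, float]], total: int) -> Dict[str, int]:
    """Largest-remainder apportionment of `total` among weighted classes."""
    raw = [(name, w * total) for name, w in weights]
    counts = {name: int(x) for name, x in raw}
    short = total - sum(counts.values())
    remainders = sorted(raw, key=lambda t: -(t[1] - int(t[1])))
    for name, _ in remainders[:short]:
        counts[name] += 1
    return counts


def generate_genes(
    spec: SynthSpec, genome: GenomeSequence
) -> Tuple[List[TranscriptModel], List[GenomeSequence], Dict]:
    """Plant non-overlapping gene loci; edit the genome in place.

    Exonic bases are overwritten with designed transcript sequence (so the
    spliced model reproduces the transcript exactly) and each intron's
    first/last two bases with the planted donor/acceptor dinucleotides,
    strand-aware. Donor counts follow the mix exactly via largest-remainder
    apportionment over all introns.
    """
    rng = spec.rng(1)
    seq = bytearray(genome.sequence, "ascii")
    lo_ex, hi_ex = spec.exons_per_gene
    min_exon = 60

    models: List[TranscriptModel] = []
    transcripts: List[GenomeSequence] = []
    gene_truth: List[Dict] = []
    intron_slots: List[Tuple[int, Tuple[int, int], str]] = []  # (gene idx, interval, strand)

    cursor = int(rng.integers(200, 600))
    for gi in range(spec.n_genes):
        tx_len = int(rng.integers(spec.transcript_length_range[0],
                                  spec.transcript_length_range[1] + 1))
        n_exons = int(rng.integers(lo_ex, hi_ex + 1))
        n_exons = max(1, min(n_exons, tx_len // min_exon))
        extra = tx_len - n_exons * min_exon
        cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1))
        parts = np.diff(np.concatenate(([0], cuts, [extra]))) + min_exon
        intron_lens = rng.integers(spec.intron_length_range[0],
                                   spec.intron_length_range[1] + 1,
                                   size=n_exons - 1)
        strand = "+" if rng.integers(0, 2) == 0 else "-"

        orf_cov = rng.uniform(0.60, 0.90)
        orf_aa = max(50, int((tx_len * orf_cov - 6) // 3))
        planted = make_transcript(rng, tx_len, orf_aa)

        # genomic layout
        exons = []
        pos = cursor
        for k, part in enumerate(parts):
            exons.append((pos, pos + int(part)))
            pos += int(part)
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        locus_end = pos
        if locus_end + 600 > len(seq):
            raise ValueError("insufficient genome space for requested genes")

        # write spliced sequence through the exon map
        fwd = planted.sequence if strand == "+" else revcomp(planted.sequence)
        off = 0
        for s, e in exons:
            seq[s:e] = fwd[off: off + (e - s)].encode("ascii")
            off += e - s

        tid = f"gene{gi:04d}.t1"
        model = TranscriptModel(tid, CHROM, strand, tuple(exons))
        models.append(model)
        transcripts.append(GenomeSequence(tid, planted.sequence))
        for iv in model.introns:
            intron_slots.append((gi, iv, strand))
        gene_truth.append({
            "id": tid, "strand": strand, "length": tx_len,
            "exons": exons,
            "orf": {"start": planted.orf_start, "end": planted.orf_end,
                    "aa": len(planted.peptide)},
            "peptide": planted.peptide,
        })
        cursor = locus_end + int(rng.integers(300, 800))

    # plant donor dinucleotides with exact counts
    counts = _apportion(spec.donor_mix, len(intron_slots))
    donor_pool = [d for d, c in counts.items() for _ in range(c)]
    donor_pool = [donor_pool[i] for i in rng.permutation(len(donor_pool))]
    junction_truth = []
    for (gi, (s, e), strand), donor in zip(intron_slots, donor_pool):
        if strand == "+":
            seq[s:s + 2] = donor.encode("ascii")
            seq[e - 2:e] = b"AG"
        else:
            seq[s:s + 2] = b"CT"  # revcomp of AG
            seq[e - 2:e] = revcomp(donor).encode("ascii")
        junction_truth.append({
            "chrom": CHROM, "start": s, "end": e, "strand": strand,
            "donor": donor, "acceptor": "AG",
        })

    genome.sequence = seq.decode("ascii")
    truth = {
        "genes": gene_truth,
        "junctions": junction_truth,
        "donor_counts": counts,
        "n_introns": len(intron_slots),
    }
    return models, transcripts, truth


# ---------------------------------------------------------------------------
# Fusions, intact controls, low-ORF decoys
# ---------------------------------------------------------------------------

def generate_fusions(
    spec: SynthSpec,
    n: Optional[int] = None,
    opposite_strand: bool = True,
) -> Tuple[List[GenomeSequence], Dict]:
    """Chimeric transcripts overlapping two genes' 3' ends.

    Each side is a standalone designed transcript carrying an ORF of at
    least 100 aa; the second side is reverse-complemented (opposite-strand
    fusion, the default) or appended in sense orientation. Parents are at
    least 2000 bp with longest-ORF coverage strictly inside (10%, 80%).
    The truth table records the intended split point and strands.
    """
    rng = spec.rng(2)
    n = spec.n_fusions if n is None else n
    fused: List[GenomeSequence] = []
    truth: List[Dict] = []
    for fi in range(n):
        for _ in range(50):
            ov = int(rng.integers(spec.fusion_overlap_range[0],
                                  spec.fusion_overlap_range[1] + 1))
            len_a = int(rng.integers(1050, 1500))
            len_b = int(rng.integers(1050, 1500))
            aa_a = int(rng.integers(105, 200))
            aa_b = int(rng.integers(105, 200))
            side_a = make_transcript(rng, len_a, aa_a, max_other_aa=99)
            core_b = 3 * aa_b + 6
            if opposite_strand:
                # joined at B's 3' end: keep a 3' tail longer than the overlap
                pad5_b = int(rng.integers(0, len_b - core_b - ov - 10))
            else:
                # joined at B's 5' end: the 5' trim must spare B's ORF
                pad5_b = int(rng.integers(ov + 10, len_b - core_b + 1))
            side_b = make_transcript(rng, len_b, aa_b, max_other_aa=99,
                                     pad5=pad5_b)
            if opposite_strand:
                tail = revcomp(side_b.sequence)[ov:]
            else:
                tail = side_b.sequence[ov:]
            parent = side_a.sequence + tail
            found = orf_mod.find_orfs(parent, min_aa=1)
            top2 = found[:2]
            want_b_strand = "-" if opposite_strand else "+"
            cov = orf_mod.orf_coverage(parent, found[0]) if found else 0.0
            if not (
                len(parent) >= 2000
                and 0.10 < cov < 0.80
                and len(top2) == 2
                and {top2[0].strand, top2[1].strand} == ({"+", want_b_strand}
                                                         if opposite_strand else {"+"})
                and all(o.aa_len < 100 for o in found[2:])
                and min(o.start for o in top2) == side_a.orf_start
            ):
                continue
            ordered = sorted(top2, key=lambda o: o.start)
            split_point = (ordered[0].end + ordered[1].start) // 2
            name = f"fusion{fi:03d}"
            fused.append(GenomeSequence(name, parent))
            truth.append({
                "id": name, "length": len(parent), "overlap": ov,
                "split_point": split_point,
                "strands": [o.strand for o in ordered],
                "opposite_strand": opposite_strand,
                "orf_intervals": [[o.start, o.end] for o in ordered],
            })
            break
        else:
            raise RuntimeError("could not construct a valid fusion")
    return fused, {"fusions": truth}


def generate_intact(spec: SynthSpec, n: int,
                    min_coverage: float = 0.85) -> List[GenomeSequence]:
    """Single-gene transcripts whose ORF covers >= min_coverage (keep controls)."""
    rng = spec.rng(5)
    out = []
    for i in range(n):
        tx_len = int(rng.integers(900, 2600))
        orf_aa = int((tx_len * min(0.97, min_coverage + 0.08) - 6) // 3)
        planted = make_transcript(rng, tx_len, orf_aa)
        out.append(GenomeSequence(f"intact{i:03d}", planted.sequence))
    return out


def generate_decoys(spec: SynthSpec, n: int, length: int = 3000) -> List[GenomeSequence]:
    """Stop-dense filler transcripts whose longest ORF covers < 10% (remove)."""
    rng = spec.rng(6)
    return [
        GenomeSequence(f"decoy{i:03d}", _filler(rng, length)) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Gold standard and a defect-planted collection
# ---------------------------------------------------------------------------

def generate_gold_fixture(
    spec: SynthSpec,
    n_gold: int = 20,
    n_frameshift: int = 2,
    n_absent: int = 1,
    length_range: Tuple[int, int] = (300, 450),
) -> Tuple[List[GenomeSequence], List[GenomeSequence], List[GenomeSequence], Dict]:
    """A curated reference set and a transcript collection with planted defects.

    Returns (gold DNA, gold peptides, collection, truth). The collection
    carries an intact copy of each gold gene except: ``n_frameshift`` genes
    get a single-base insertion mid-ORF (protein broken, DNA nearly intact)
    and ``n_absent`` genes are dropped entirely — the mechanism by which
    genes present at the DNA level vanish at the protein level.

    Gene lengths default to 300-450 bp: long enough that an intact copy
    clears the score-200 presence cutoff outright, short enough that the
    exhaustive aligner's chance score between unrelated sequences (which
    grows linearly with length under gap-event-only penalties) stays well
    below it.
    """
    rng = spec.rng(4)
    gold: List[GenomeSequence] = []
    gold_pep: List[GenomeSequence] = []
    for i in range(n_gold):
        tx_len = int(rng.integers(length_range[0], length_range[1] + 1))
        orf_aa = int((tx_len * 0.85 - 6) // 3)
        planted = make_transcript(rng, tx_len, orf_aa)
        gold.append(GenomeSequence(f"gold{i:02d}", planted.sequence))
        gold_pep.append(GenomeSequence(f"gold{i:02d}", planted.peptide))

    roles = ["intact"] * n_gold
    picks = rng.permutation(n_gold)[: n_frameshift + n_absent]
    for j in picks[:n_frameshift]:
        roles[j] = "frameshift"
    for j in picks[n_frameshift:]:
        roles[j] = "absent"

    collection: List[GenomeSequence] = []
    for g, pep, role in zip(gold, gold_pep, roles):
        if role == "absent":
            continue
        seq = g.sequence
        if role == "frameshift":
            orf = orf_mod.longest_orf(seq)
            pos = orf.start + (orf.nt_len // 2 // 3) * 3 + 1
            ins = "G" if seq[pos] != "G" else "C"
            seq = seq[:pos] + ins + seq[pos:]
        collection.append(GenomeSequence(f"tx_{g.name}", seq))
    truth = {"roles": dict(zip((g.name for g in gold), roles)), "n_gold": n_gold}
    return gold, gold_pep, collection, truth


# ---------------------------------------------------------------------------
# Coverage with planted retention and unexplained regions
# ---------------------------------------------------------------------------

def generate_coverage(
    spec: SynthSpec,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> Tuple[CoverageTrack, Dict]:
    """Depth track with exact planted retention and unexplained regions.

    Exonic bases get the spec read depth. A ``retention_rate`` fraction of
    introns (rounded to the nearest count) is covered end-to-end at depths
    in 1..5; every other intron keeps a zero-depth gap in its middle.
    ``n_unexplained`` intervals of the spec length and depth are painted in
    intergenic space, flanked by zero coverage.
    """
    rng = spec.rng(3)
    track = CoverageTrack({genome.name: len(genome)})
    depth = track[genome.name]

    introns: List[Tuple[int, int]] = []
    for m in models:
        for s, e in m.exons:
            depth[s:e] = spec.read_depth
        introns.extend(m.introns)

    n_retained = int(round(spec.retention_rate * len(introns)))
    order = rng.permutation(len(introns))
    retained_idx = set(order[:n_retained].tolist())
    retention_truth = []
    for i, (s, e) in enumerate(introns):
        low = int(rng.integers(1, 6))
        if i in retained_idx:
            depth[s:e] = low
            retained = True
        else:
            depth[s:e] = low
            gap = max(1, (e - s) // 5)
            mid = (s + e) // 2
            depth[mid - gap // 2: mid - gap // 2 + gap] = 0
            retained = False
        retention_truth.append(
            {"start": s, "end": e, "retained": retained, "depth": low}
        )

    # unexplained regions in intergenic gaps (>=100 bp clear of any model span)
    spans = sorted(m.span for m in models)
    gaps = []
    prev = 0
    for s, e in spans:
        gaps.append((prev, s))
        prev = max(prev, e)
    gaps.append((prev, len(genome)))
    need = spec.unexplained_length + 200  # region plus 100 bp zero margins
    gaps.sort(key=lambda g: g[0] - g[1])  # largest first
    unexplained_truth = []
    for gs, ge in gaps:
        cursor = gs
        while (
            len(unexplained_truth) < spec.n_unexplained
            and ge - cursor >= need
        ):
            start = cursor + 100
            end = start + spec.unexplained_length
            depth[start:end] = spec.unexplained_depth
            unexplained_truth.append({"chrom": genome.name, "start": start,
                                      "end": end, "depth": spec.unexplained_depth})
            cursor = end + 100
        if len(unexplained_truth) == spec.n_unexplained:
            break
    if len(unexplained_truth) < spec.n_unexplained:
        raise ValueError("not enough intergenic space for unexplained regions")
    unexplained_truth.sort(key=lambda r: r["start"])

    truth = {
        "retention": retention_truth,
        "n_retained": n_retained,
        "n_introns": len(introns),
        "unexplained": unexplained_truth,
    }
    return track, truth


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def generate_bundle(spec: SynthSpec, outdir: str | os.PathLike) -> Dict:
    """Write the full fixture bundle and return the combined truth table.

    Files: genome.fasta, models.gtf, transcripts.fasta, fused.fasta,
    coverage.bedgraph, gold.fasta, gold.pep.fasta, truth.json.
    """
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(spec)
    models, transcripts, gene_truth = generate_genes(spec, genome)
    fused, fusion_truth = generate_fusions(spec)
    track, cov_truth = generate_coverage(spec, models, genome)
    gold, gold_pep, gold_coll, gold_truth = generate_gold_fixture(spec)

    write_fasta([genome], os.path.join(outdir, "genome.fasta"))
    write_gtf(models, os.path.join(outdir, "models.gtf"))
    write_fasta(transcripts, os.path.join(outdir, "transcripts.fasta"))
    write_fasta(fused, os.path.join(outdir, "fused.fasta"))
    write_bedgraph(track, os.path.join(outdir, "coverage.bedgraph"))
    write_fasta(gold, os.path.join(outdir, "gold.fasta"))
    write_fasta(gold_pep, os.path.join(outdir, "gold.pep.fasta"))
    write_fasta(gold_coll, os.path.join(outdir, "collection.fasta"))

    truth = {
        "spec": asdict(spec),
        **gene_truth,
        **fusion_truth,
        **cov_truth,
        "gold": gold_truth,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
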