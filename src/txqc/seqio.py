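"""Readers and writers for FASTA, GTF, BED and coverage tracks.

All coordinates inside the toolkit are 0-based, half-open intervals.
Conversion to and from the 1-based inclusive conventions of GTF and
fixedStep wiggle happens only in this module, at the file boundary.
BED and bedGraph are already 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

#: Smallest intron the toolkit accepts, matching the spliced-aligner setting
#: used to build the transcript models this toolkit consumes.
DEFAULT_MIN_INTRON = 30


class SeqioError(ValueError):
    """Malformed input file or inconsistent genomic coordinates."""


@dataclass
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on read."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as ordered, non-overlapping exon intervals on a chromosome.

    ``strand`` is '+', '-' or '?' (unknown, e.g. unoriented EST alignments).
    Exons are 0-based half-open genomic intervals sorted by start.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-", "?"):
            raise SeqioError(f"invalid strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise SeqioError(
                    f"{self.transcript_id}: empty/inverted exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise SeqioError(f"{self.transcript_id}: overlapping exons")
            prev_end = end
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive exons, 0-based half-open."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def spliced_sequence(self, genome: Dict[str, GenomeSequence]) -> str:
        """Exon concatenation, reverse-complemented for '-' strand."""
        seq = genome[self.chrom].sequence
        joined = "".join(seq[s:e] for s, e in self.exons)
        if self.strand == "-":
            return str(Seq(joined).reverse_complement())
        return joined


class CoverageTrack:
    """Dense per-base read depth over named sequences.

    Positions absent from the source file have depth 0; depths are
    non-negative integers.
    """

    def __init__(self, lengths: Dict[str, int]):
        self.depth: Dict[str, np.ndarray] = {
            name: np.zeros(n, dtype=np.int64) for name, n in lengths.items()
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depth[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depth

    def chroms(self) -> List[str]:
        return list(self.depth)

    def total(self) -> int:
        return int(sum(v.sum() for v in self.depth.values()))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> List[GenomeSequence]:
    """Read a (multi-)FASTA into GenomeSequence records, order preserved.

    Sequences are uppercased. Duplicate identifiers and empty sequences
    are errors; characters are not restricted here because the same reader
    serves peptide FASTA (the DNA alphabet is enforced by consumers that
    require it).
    """
    records: List[GenomeSequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SeqioError(f"{path}: malformed/empty FASTA header")
        if rec.id in seen:
            raise SeqioError(f"{path}: duplicate identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise SeqioError(f"{path}: empty sequence for {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def as_genome_dict(records: Iterable[GenomeSequence]) -> Dict[str, GenomeSequence]:
    out = {}
    for r in records:
        if r.name in out:
            raise SeqioError(f"duplicate sequence name {r.name!r}")
        out[r.name] = r
    return out


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike,
             min_intron: int | None = None) -> List[TranscriptModel]:
    """Read GTF exon features into transcript models.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention. Exons are grouped by ``transcript_id``, sorted by
    start; the result is invariant under permutation of the input lines.
    Transcripts appear in order of first occurrence.

    If ``min_intron`` is given, any transcript with an exon gap shorter than
    that is rejected.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    by_tx: Dict[str, List[Tuple[int, int]]] = {}
    chrom_strand: Dict[str, Tuple[str, str]] = {}
    order: List[str] = []
    for feat in db.features_of_type("exon", order_by=None):
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise SeqioError(f"{path}: exon feature without transcript_id")
        tid = tids[0]
        if feat.end < feat.start:
            raise SeqioError(f"{path}: exon end < start for {tid!r}")
        start0, end0 = feat.start - 1, feat.end  # 1-based incl -> 0-based half-open
        strand = feat.strand if feat.strand in ("+", "-") else "?"
        if tid not in by_tx:
            by_tx[tid] = []
            chrom_strand[tid] = (feat.seqid, strand)
            order.append(tid)
        else:
            if chrom_strand[tid][0] != feat.seqid:
                raise SeqioError(f"{path}: {tid!r} spans multiple chromosomes")
        by_tx[tid].append((start0, end0))

    models = []
    for tid in order:
        exons = sorted(by_tx[tid])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise SeqioError(f"{path}: overlapping exons in {tid!r}")
            if min_intron is not None and s2 - e1 < min_intron:
                raise SeqioError(
                    f"{path}: {tid!r} intron of length {s2 - e1} < {min_intron}"
                )
        chrom, strand = chrom_strand[tid]
        models.append(TranscriptModel(tid, chrom, strand, tuple(exons)))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "txqc") -> None:
    """Write exon features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for m in models:
            strand = m.strand if m.strand in ("+", "-") else "."
            for start, end in m.exons:
                attrs = f'gene_id "{m.transcript_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> List[Tuple[str, int, int]]:
    """Read BED3+ intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SeqioError(f"{path}: BED line with <3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise SeqioError(f"{path}: BED end < start")
            out.append((chrom, start, end))
    return out


def write_bed(intervals: Iterable[Sequence], path: str | os.PathLike) -> None:
    """Write BED lines; each interval is (chrom, start, end[, name, score, strand])."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# Coverage (bedGraph / fixedStep wiggle)
# ---------------------------------------------------------------------------

def read_coverage(path: str | os.PathLike,
                  genome: Dict[str, GenomeSequence]) -> CoverageTrack:
    """Read a bedGraph or fixedStep wiggle file into a dense CoverageTrack.

    The format is sniffed from the first data line. bedGraph records are
    0-based half-open; fixedStep declarations are 1-based. Overlapping
    bedGraph records, unknown chromosomes, negative depths and records
    beyond the chromosome end are errors.
    """
    track = CoverageTrack({name: len(g) for name, g in genome.items()})
    painted = {name: np.zeros(len(g), dtype=bool) for name, g in genome.items()}

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    is_wiggle = any(ln.startswith("fixedStep") for ln in lines)
    if is_wiggle:
        _read_fixedstep(lines, path, track)
        return track

    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith(("track", "#", "browser")):
            continue
        fields = ln.split()
        if len(fields) != 4:
            raise SeqioError(f"{path}: bedGraph line needs 4 fields: {ln!r}")
        chrom, start, end, depth = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
        if chrom not in track:
            raise SeqioError(f"{path}: unknown chromosome {chrom!r}")
        if depth < 0:
            raise SeqioError(f"{path}: negative depth on {chrom}:{start}-{end}")
        if end > len(track[chrom]) or start < 0 or end < start:
            raise SeqioError(f"{path}: record beyond chromosome end: {ln!r}")
        if painted[chrom][start:end].any():
            raise SeqioError(f"{path}: overlapping bedGraph records at {chrom}:{start}")
        painted[chrom][start:end] = True
        track[chrom][start:end] = depth
    return track


def _read_fixedstep(lines: List[str], path, track: CoverageTrack) -> None:
    chrom, pos, step = None, 0, 1
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith(("track", "#")):
            continue
        if ln.startswith("fixedStep"):
            kv = dict(item.split("=") for item in ln.split()[1:])
            chrom = kv["chrom"]
            if chrom not in track:
                raise SeqioError(f"{path}: unknown chromosome {chrom!r}")
            pos = int(kv["start"]) - 1  # wiggle is 1-based
            step = int(kv.get("step", 1))
            continue
        if chrom is None:
            raise SeqioError(f"{path}: wiggle data before fixedStep header")
        depth = int(float(ln))
        if depth < 0:
            raise SeqioError(f"{path}: negative depth at {chrom}:{pos}")
        if pos >= len(track[chrom]):
            raise SeqioError(f"{path}: record beyond chromosome end")
        track[chrom][pos] = depth
        pos += step


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write non-zero depth runs as bedGraph records (run-length encoded)."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            depth = track[chrom]
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(depth)]))
            for s, e in zip(starts, ends):
                d = int(depth[s])
                if d != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")
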