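"""Splice-junction extraction, deduplication and donor/acceptor tallies.

In GC-rich genomes the canonical GT-AG intron signal can give way to GC-AG
as the dominant donor class; this module recovers the donor/acceptor
dinucleotide landscape of a transcript collection directly from its models
and the genome. Donor and acceptor are strand-orientational: the donor is
the first two intronic bases in transcription direction, the acceptor the
last two; on the '-' strand both are reverse-complemented from the forward
genome sequence.

Junction identity for deduplication is (chrom, intron interval, strand), so
alternate isoforms sharing an intron contribute a single junction.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

from .orf import revcomp
from .seqio import DEFAULT_MIN_INTRON, GenomeSequence, TranscriptModel

DONOR_BINS = ("GC", "GT", "GA", "AT", "CT")
ACCEPTOR_BINS = ("AG", "AC", "GC", "AT")
OTHER = "other"


@dataclass(frozen=True)
class Junction:
    chrom: str
    start: int  # 0-based half-open intron interval on the forward strand
    end: int
    strand: str
    donor_dinuc: str
    acceptor_dinuc: str

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class JunctionTally:
    donors: Dict[str, int]
    acceptors: Dict[str, int]
    total: int

    def donor_percentages(self) -> Dict[str, int]:
        return {k: round(100 * v / self.total) for k, v in self.donors.items()}

    def acceptor_percentages(self) -> Dict[str, int]:
        return {k: round(100 * v / self.total) for k, v in self.acceptors.items()}


def _dinucs(seq: str, start: int, end: int, strand: str) -> tuple[str, str]:
    first, last = seq[start:start + 2], seq[end - 2:end]
    if strand == "-":
        return revcomp(last), revcomp(first)
    return first, last


def _majority_strand(model: TranscriptModel, seq: str) -> str:
    fwd = sum(1 for s, e in model.introns if seq[e - 2:e] == "AG")
    rev = sum(1 for s, e in model.introns if seq[s:s + 2] == "CT")
    if fwd > rev:
        return "+"
    if rev > fwd:
        return "-"
    return "?"


def infer_strand_by_acceptor(model: TranscriptModel,
                             genome: Dict[str, GenomeSequence]) -> str:
    """Orient a strand-unknown model by its acceptor dinucleotides.

    '+' if the majority of introns end in AG read forward, '-' if the
    majority start with CT (AG read reverse-complemented), '?' on a tie.
    """
    if not model.introns:
        raise ValueError(f"{model.transcript_id}: no introns to orient by")
    return _majority_strand(model, genome[model.chrom].sequence)


def extract_junctions(
    models: Iterable[TranscriptModel],
    genome: Dict[str, GenomeSequence],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> Set[Junction]:
    """One Junction per unique (chrom, intron interval, strand).

    Introns shorter than ``min_intron`` are rejected with a warning. Models
    with unknown strand are oriented by their acceptors
    (:func:`infer_strand_by_acceptor`); if that ties, '+' is assumed.
    """
    out: Set[Junction] = set()
    for model in models:
        if model.chrom not in genome:
            raise KeyError(f"chromosome {model.chrom!r} not in genome")
        seq = genome[model.chrom].sequence
        strand = model.strand
        if strand == "?" and model.introns:
            strand = _majority_strand(model, seq)
            if strand == "?":
                strand = "+"
        for start, end in model.introns:
            if end > len(seq) or start < 0:
                raise ValueError(
                    f"{model.transcript_id}: intron [{start},{end}) out of bounds"
                )
            if end - start < min_intron:
                warnings.warn(
                    f"{model.transcript_id}: intron of length {end - start} "
                    f"< {min_intron} skipped"
                )
                continue
            donor, acceptor = _dinucs(seq, start, end, strand)
            out.add(Junction(model.chrom, start, end, strand, donor, acceptor))
    return out


def _bin(dinuc: str, bins: Sequence[str]) -> str:
    if "N" in dinuc or dinuc not in bins:
        return OTHER
    return dinuc


def classify(junction_set: Iterable[Junction]) -> JunctionTally:
    """Tally donors into {GC, GT, GA, AT, CT, other} and acceptors into
    {AG, AC, GC, AT, other}; dinucleotides containing N go to 'other'."""
    junctions = list(junction_set)
    if not junctions:
        raise ValueError("empty junction set")
    donors = Counter(_bin(j.donor_dinuc, DONOR_BINS) for j in junctions)
    acceptors = Counter(_bin(j.acceptor_dinuc, ACCEPTOR_BINS) for j in junctions)
    return JunctionTally(
        donors={k: donors.get(k, 0) for k in (*DONOR_BINS, OTHER)},
        acceptors={k: acceptors.get(k, 0) for k in (*ACCEPTOR_BINS, OTHER)},
        total=len(junctions),
    )


def filter_ag_acceptors(junction_set: Iterable[Junction]) -> Set[Junction]:
    """Noise filter for EST-derived junctions: keep only AG acceptors."""
    return {j for j in junction_set if j.acceptor_dinuc == "AG"}


def junctions_to_bed(junctions: Iterable[Junction]) -> List[tuple]:
    """BED6 rows (name = donor-acceptor), sorted by position."""
    rows = [
        (j.chrom, j.start, j.end, f"{j.donor_dinuc}-{j.acceptor_dinuc}", 0, j.strand)
        for j in junctions
    ]
    return sorted(rows)
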