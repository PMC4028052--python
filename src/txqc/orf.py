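"""Six-frame ORF enumeration with a stop-to-stop convention.

Fragmented transcript collections rarely carry complete 5' ends, so the
default ORF definition here is *stop-to-stop*: a maximal codon run bounded
by stop codons, with sequence ends acting as boundaries and no initial
methionine required. The conventional Met-to-stop definition is available
as an alternative mode; every Met-to-stop ORF is a suffix of some
stop-to-stop ORF, starting at its first methionine.

Codons containing N translate to X, and X never terminates an ORF:
draft-genome holes must not shatter reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOP_CODONS = frozenset(_TABLE.stop_codons)

STOP_TO_STOP = "stop_to_stop"
MET_TO_STOP = "met_to_stop"
MODES = (STOP_TO_STOP, MET_TO_STOP)

_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Translate one codon; '*' for a definite stop, 'X' if it contains N."""
    if codon in _CODON_TO_AA:
        return _CODON_TO_AA[codon]
    if codon in _STOP_CODONS:
        return "*"
    return "X"  # contains N; never a stop


@dataclass(frozen=True)
class Orf:
    """An open reading frame located on a transcript.

    ``start``/``end`` are 0-based half-open on the transcript's *forward*
    coordinates regardless of strand; the interval includes the terminal
    stop codon when one is present (so translating the oriented interval
    yields ``peptide`` plus an optional trailing '*'). ``frame`` is the
    offset of the first codon within the strand-oriented sequence.
    """

    strand: str
    frame: int
    start: int
    end: int
    mode: str
    peptide: str

    @property
    def aa_len(self) -> int:
        return len(self.peptide)

    @property
    def nt_len(self) -> int:
        return self.end - self.start


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def find_orfs(sequence: str, mode: str = STOP_TO_STOP, min_aa: int = 1) -> List[Orf]:
    """Enumerate maximal ORFs in all six frames.

    Returns ORFs with peptide length >= ``min_aa``, sorted by peptide length
    descending; ties broken by strand ('+' first), then smaller forward start.
    Trailing bases short of a full codon are ignored.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if min_aa < 0:
        raise ValueError("min_aa must be >= 0")
    seq = _validate(sequence)
    n = len(seq)
    orfs: List[Orf] = []
    for strand in ("+", "-"):
        work = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            n_codons = (n - frame) // 3
            if n_codons <= 0:
                continue
            aa = "".join(
                translate_codon(work[frame + 3 * i: frame + 3 * i + 3])
                for i in range(n_codons)
            )
            orfs.extend(
                _frame_orfs(aa, strand, frame, n, mode, min_aa)
            )
    orfs.sort(key=lambda o: (-o.aa_len, o.strand != "+", o.start))
    return orfs


def _frame_orfs(aa: str, strand: str, frame: int, seqlen: int,
                mode: str, min_aa: int) -> List[Orf]:
    """Maximal stop-bounded runs within one translated frame."""
    out = []
    run_start = 0  # codon index where the current run begins
    n_codons = len(aa)
    for i in range(n_codons + 1):
        at_end = i == n_codons
        if at_end or aa[i] == "*":
            pep = aa[run_start:i]
            codon_lo, codon_hi = run_start, i + (0 if at_end else 1)
            if mode == MET_TO_STOP:
                m = pep.find("M")
                if m >= 0:
                    pep = pep[m:]
                    codon_lo = run_start + m
                else:
                    pep = ""
            if pep and len(pep) >= min_aa:
                out.append(_locate(strand, frame, codon_lo, codon_hi,
                                   seqlen, mode, pep))
            run_start = i + 1
    return out


def _locate(strand: str, frame: int, codon_lo: int, codon_hi: int,
            seqlen: int, mode: str, pep: str) -> Orf:
    s = frame + 3 * codon_lo
    e = frame + 3 * codon_hi
    if strand == "-":
        s, e = seqlen - e, seqlen - s
    return Orf(strand, frame, s, e, mode, pep)


def longest_orf(sequence: str, mode: str = STOP_TO_STOP) -> Optional[Orf]:
    """The top ORF under find_orfs ordering; None if no ORF of >= 1 aa exists."""
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    hits = find_orfs(sequence, mode=mode, min_aa=1)
    return hits[0] if hits else None


def orf_coverage(sequence: str, orf: Optional[Orf]) -> float:
    """Fraction of the transcript occupied by the ORF interval, in [0, 1].

    None (no ORF found) counts as coverage 0.
    """
    if orf is None:
        return 0.0
    if orf.start < 0 or orf.end > len(sequence):
        raise ValueError("ORF interval outside sequence")
    return orf.nt_len / len(sequence)
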