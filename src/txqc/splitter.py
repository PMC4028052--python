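"""Detection and splitting of artificially fused transcripts.

Assemblers working on compact genomes frequently join two genes into one
contig, typically where 3'UTRs of opposite-strand gene pairs overlap. Such
chimeras betray themselves through ORF geometry: no single reading frame
covers the sequence, but two (or three) long, mutually non-overlapping ORFs
do. The rules applied here, in order:

1. If the longest ORF covers less than ``remove_cov`` (default 10%) of the
   sequence, the transcript is removed (junk with no credible coding run).
2. If it covers at least ``keep_cov`` (default 80%), the transcript is kept.
3. Transcripts shorter than ``min_parent_len`` (default 2000 bp) are kept.
4. Otherwise the top ``max_orfs`` (default 3) ORFs with peptides of at least
   ``min_peptide_aa`` (default 100 aa) are examined; if two or three of them
   occupy pairwise non-overlapping intervals and every resulting child is at
   least ``min_child_len`` (default 300 bp), the transcript is split between
   them.

Cuts are placed at the midpoint of the gap between consecutive participating
ORFs, so each child keeps its flanking UTR-like sequence symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

from . import orf as orf_mod
from .orf import Orf, STOP_TO_STOP
from .seqio import GenomeSequence


@dataclass(frozen=True)
class SplitParams:
    keep_cov: float = 0.80
    remove_cov: float = 0.10
    min_parent_len: int = 2000
    min_child_len: int = 300
    min_peptide_aa: int = 100
    max_orfs: int = 3

    def __post_init__(self):
        if not self.remove_cov < self.keep_cov:
            raise ValueError("remove_cov must be < keep_cov")


@dataclass
class SplitDecision:
    """Outcome of the fusion check on one transcript.

    ``children`` are 0-based half-open intervals on the parent (empty unless
    the verdict is a split); ``participating_orfs`` are the ORFs justifying
    the verdict; ``opposite_strand_flag`` marks participating ORFs on both
    strands — the signature of the opposite-strand 3'UTR-overlap fusion.
    """

    verdict: str  # keep | split2 | split3 | remove
    children: List[Tuple[int, int]] = field(default_factory=list)
    participating_orfs: List[Orf] = field(default_factory=list)
    opposite_strand_flag: bool = False


def _disjoint(a: Orf, b: Orf) -> bool:
    return a.end <= b.start or b.end <= a.start


def _children_from(orfs: Sequence[Orf], parent_len: int) -> List[Tuple[int, int]]:
    """Cut at gap midpoints between consecutive (sorted) ORF intervals."""
    ordered = sorted(orfs, key=lambda o: o.start)
    cuts = [
        (left.end + right.start) // 2
        for left, right in zip(ordered, ordered[1:])
    ]
    bounds = [0] + cuts + [parent_len]
    return list(zip(bounds, bounds[1:]))


def decide_split(sequence: str, params: SplitParams = SplitParams()) -> SplitDecision:
    """Apply the fusion rules to one transcript sequence.

    Every input yields a verdict; ORFs are stop-to-stop (both strands).
    """
    top = orf_mod.find_orfs(sequence, mode=STOP_TO_STOP, min_aa=1)
    coverage = orf_mod.orf_coverage(sequence, top[0]) if top else 0.0

    if coverage < params.remove_cov:
        return SplitDecision("remove")
    if coverage >= params.keep_cov:
        return SplitDecision("keep")
    if len(sequence) < params.min_parent_len:
        return SplitDecision("keep")

    candidates = [
        o for o in top[: params.max_orfs] if o.aa_len >= params.min_peptide_aa
    ]

    def qualifies(group: Sequence[Orf]) -> List[Tuple[int, int]] | None:
        if not all(_disjoint(a, b) for a, b in combinations(group, 2)):
            return None
        kids = _children_from(group, len(sequence))
        if all(e - s >= params.min_child_len for s, e in kids):
            return kids
        return None

    # Prefer a three-way split, then the best qualifying pair: highest total
    # peptide length, ties broken by leftmost ORF start.
    for size in (3, 2):
        best = None
        for group in combinations(candidates, size):
            kids = qualifies(group)
            if kids is None:
                continue
            key = (-sum(o.aa_len for o in group), min(o.start for o in group))
            if best is None or key < best[0]:
                best = (key, group, kids)
        if best is not None:
            _, group, kids = best
            return _split_decision(list(group), kids)

    return SplitDecision("keep")


def _split_decision(orfs: List[Orf], children: List[Tuple[int, int]]) -> SplitDecision:
    ordered = sorted(orfs, key=lambda o: o.start)
    return SplitDecision(
        verdict=f"split{len(children)}",
        children=children,
        participating_orfs=ordered,
        opposite_strand_flag=len({o.strand for o in ordered}) > 1,
    )


def split_collection(
    records: Sequence[GenomeSequence],
    params: SplitParams = SplitParams(),
) -> Tuple[List[GenomeSequence], Dict[str, int]]:
    """Apply decide_split to a collection.

    Kept transcripts pass through unchanged; split children are emitted as
    ``parent_id.1``, ``parent_id.2``, ... ordered by position; removed
    transcripts are dropped. The report tallies verdicts and the number of
    splits whose participating ORFs lie on opposite strands.
    """
    out: List[GenomeSequence] = []
    report = {"keep": 0, "split2": 0, "split3": 0, "removed": 0, "opposite_strand": 0}
    for rec in records:
        decision = decide_split(rec.sequence, params)
        if decision.verdict == "keep":
            report["keep"] += 1
            out.append(rec)
        elif decision.verdict == "remove":
            report["removed"] += 1
        else:
            report[decision.verdict] += 1
            if decision.opposite_strand_flag:
                report["opposite_strand"] += 1
            for i, (s, e) in enumerate(decision.children, start=1):
                out.append(GenomeSequence(f"{rec.name}.{i}", rec.sequence[s:e]))
    return out, report
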