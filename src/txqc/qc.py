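"""Reference-gene presence QC and collection characterization.

A small set of manually curated "gold standard" genes is the yardstick: after
each pipeline stage, each curated gene is searched for in the transcript
collection with a local aligner whose hit score is

    score = matches - mismatches - (gap openings in query) - (gap openings in target)

and a gene counts as found at the DNA level when its best hit score reaches a
threshold (default 200). At the protein level — where frameshifts and
wrong-frame translations silently lose genes that are intact at the DNA
level — a gene counts as found when some translated peptide aligns over at
least ``min_coverage`` of the reference peptide at ``min_identity`` or
better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from . import orf as orf_mod
from .seqio import GenomeSequence

DNA_CHARS = frozenset("ACGTN")

FOUND = "found"
MISSING = "missing"
NO_INPUT_SUPPORT = "no_input_support"


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -1  # charged once per gap event, no length penalty


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    matches: int
    mismatches: int
    q_gap_count: int  # gap openings in the query row
    t_gap_count: int  # gap openings in the target row
    q_interval: Tuple[int, int]
    t_interval: Tuple[int, int]
    score: int
    gap_bases: int = 0  # total gap characters across both rows

    @property
    def identity(self) -> float:
        """Matches over all alignment columns, gap columns included.

        Gap extension is free in the hit score, so an exhaustive aligner
        happily chains short chance matches across unrelated sequences with
        long gaps; counting gap columns in the denominator keeps identity
        meaningful (chance chains score low, true near-exact matches stay
        near 1).
        """
        denom = self.matches + self.mismatches + self.gap_bases
        return self.matches / denom if denom else 0.0

    def query_coverage(self, query_len: int) -> float:
        return (self.q_interval[1] - self.q_interval[0]) / query_len


def _alphabet_class(seq: str) -> str:
    return "dna" if set(seq.upper()) <= DNA_CHARS else "protein"


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = 0
    return aligner


def align_local(query: GenomeSequence, target: GenomeSequence,
                scoring: Scoring = Scoring()) -> AlignmentHit:
    """Best local alignment under match/mismatch/per-gap-event scoring.

    Both sequences must be of the same alphabet class (both DNA or both
    protein). Deterministic: of co-optimal alignments the engine's first
    traceback is reported.
    """
    q, t = query.sequence.upper(), target.sequence.upper()
    if not q or not t:
        raise ValueError("empty sequence")
    if _alphabet_class(q) != _alphabet_class(t):
        raise ValueError("mixed alphabets: one DNA, one protein")
    aligner = _make_aligner(scoring)
    score = int(aligner.score(q, t))
    if score <= 0:
        return AlignmentHit(query.name, target.name, 0, 0, 0, 0, (0, 0), (0, 0), 0)
    aln = aligner.align(q, t)[0]
    q_blocks, t_blocks = aln.aligned
    matches = mismatches = q_gaps = t_gaps = gap_bases = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for cq, ct in zip(q[qs:qe], t[ts:te]):
            if cq == ct:
                matches += 1
            else:
                mismatches += 1
    for i in range(1, len(q_blocks)):
        dq = int(q_blocks[i][0] - q_blocks[i - 1][1])
        dt = int(t_blocks[i][0] - t_blocks[i - 1][1])
        if dt > 0:  # unaligned target bases: gap run in the query row
            q_gaps += 1
        if dq > 0:  # unaligned query bases: gap run in the target row
            t_gaps += 1
        gap_bases += dq + dt
    hit = AlignmentHit(
        query.name, target.name, matches, mismatches, q_gaps, t_gaps,
        (int(q_blocks[0][0]), int(q_blocks[-1][1])),
        (int(t_blocks[0][0]), int(t_blocks[-1][1])),
        matches - mismatches - q_gaps - t_gaps,
        gap_bases,
    )
    assert hit.score == score, "alignment bookkeeping out of sync with engine"
    return hit


@dataclass
class PresenceReport:
    """Per-gene, per-collection presence status plus a Venn-ready matrix."""

    status: pd.DataFrame       # genes x collections, values in {found, missing, no_input_support}
    membership: pd.DataFrame   # genes x collections, bool (found)
    best_hits: Dict[Tuple[str, str], Optional[AlignmentHit]]

    def found_counts(self) -> pd.Series:
        return self.membership.sum(axis=0)

    def venn_counts(self) -> Dict[Tuple[str, ...], int]:
        """Count genes by the exact subset of collections they were found in."""
        out: Dict[Tuple[str, ...], int] = {}
        for _, row in self.membership.iterrows():
            key = tuple(c for c in self.membership.columns if row[c])
            out[key] = out.get(key, 0) + 1
        return out


def presence_check(
    references: Sequence[GenomeSequence],
    collections: Dict[str, Sequence[GenomeSequence]],
    level: str = "dna",
    min_score: int = 200,
    min_coverage: float = 0.80,
    min_identity: float = 0.95,
    eligibility: Optional[Dict[str, Iterable[str]]] = None,
    scoring: Scoring = Scoring(),
) -> PresenceReport:
    """Check each reference gene for presence in each collection.

    ``level='dna'``: found iff some collection sequence attains hit score
    >= ``min_score``. ``level='protein'``: references and collections are
    peptides; found iff some hit covers >= ``min_coverage`` of the reference
    at >= ``min_identity`` identity.

    ``eligibility`` optionally restricts, per collection, which reference
    genes have enough input support to be findable at all (e.g. genes with
    too few reads); ineligible genes get status ``no_input_support`` and are
    excluded from the membership matrix denominators.
    """
    if level not in ("dna", "protein"):
        raise ValueError(f"unknown level {level!r}")
    if not references:
        raise ValueError("empty reference set")
    gene_ids = [r.name for r in references]
    coll_names = list(collections)
    status = pd.DataFrame(MISSING, index=gene_ids, columns=coll_names)
    best_hits: Dict[Tuple[str, str], Optional[AlignmentHit]] = {}

    for cname, members in collections.items():
        if not members:
            warnings.warn(f"collection {cname!r} is empty; all genes missing")
        eligible = set(eligibility[cname]) if eligibility and cname in eligibility else None
        for ref in references:
            if eligible is not None and ref.name not in eligible:
                status.loc[ref.name, cname] = NO_INPUT_SUPPORT
                best_hits[(ref.name, cname)] = None
                continue
            best: Optional[AlignmentHit] = None
            for member in members:
                hit = align_local(ref, member, scoring)
                if best is None or hit.score > best.score:
                    best = hit
            best_hits[(ref.name, cname)] = best
            if best is None:
                continue
            if level == "dna":
                ok = best.score >= min_score
            else:
                ok = (
                    best.query_coverage(len(ref.sequence)) >= min_coverage
                    and best.identity >= min_identity
                )
            if ok:
                status.loc[ref.name, cname] = FOUND

    membership = status == FOUND
    return PresenceReport(status, membership, best_hits)


def translate_collection(records: Sequence[GenomeSequence],
                         mode: str = orf_mod.STOP_TO_STOP) -> List[GenomeSequence]:
    """Longest-ORF peptide per transcript, for protein-level QC.

    Transcripts with no ORF are dropped.
    """
    out = []
    for rec in records:
        if len(rec.sequence) < 3:
            continue
        top = orf_mod.longest_orf(rec.sequence, mode=mode)
        if top is not None and top.peptide:
            out.append(GenomeSequence(rec.name, top.peptide))
    return out


@dataclass
class CollectionStats:
    n: int
    length_hist: Dict[str, int]
    coverage_hist: Dict[str, int]
    median_length: float
    median_orf_aa: float
    median_orf_coverage: float
    lengths: List[int] = field(repr=False, default_factory=list)
    orf_coverages: List[float] = field(repr=False, default_factory=list)


def characterize_collection(
    records: Sequence[GenomeSequence],
    length_edges: Sequence[int] = (500, 1000),
    n_coverage_bins: int = 10,
) -> CollectionStats:
    """Length and ORF-coverage profile of a transcript collection.

    Length bins are (0, e1], (e1, e2], ..., (ek, inf); coverage bins are
    equal-width over [0, 1] with the top bin closed at 1.0.
    """
    lengths = [len(r.sequence) for r in records]
    covs, aas = [], []
    for r in records:
        top = orf_mod.longest_orf(r.sequence) if len(r.sequence) >= 3 else None
        covs.append(orf_mod.orf_coverage(r.sequence, top))
        aas.append(top.aa_len if top else 0)

    edges = [0, *length_edges, np.inf]
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f">{int(lo)}" if np.isinf(hi) else f"{int(lo) + 1}-{int(hi)}")
    length_hist = {lab: 0 for lab in labels}
    for n in lengths:
        for lab, lo, hi in zip(labels, edges, edges[1:]):
            if lo < n <= hi:
                length_hist[lab] += 1
                break

    cov_edges = np.linspace(0.0, 1.0, n_coverage_bins + 1)
    cov_counts, _ = np.histogram(covs, bins=cov_edges)
    coverage_hist = {
        f"{cov_edges[i]:.1f}-{cov_edges[i + 1]:.1f}": int(cov_counts[i])
        for i in range(n_coverage_bins)
    }

    return CollectionStats(
        n=len(records),
        length_hist=length_hist,
        coverage_hist=coverage_hist,
        median_length=float(np.median(lengths)) if lengths else float("nan"),
        median_orf_aa=float(np.median(aas)) if aas else float("nan"),
        median_orf_coverage=float(np.median(covs)) if covs else float("nan"),
        lengths=lengths,
        orf_coverages=covs,
    )
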