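"""Redundancy removal and identical-or-contained merging of collections.

Two operations recur when integrating several assembly arms:

* ``dedupe`` — greedy longest-first clustering: each sequence joins the first
  cluster whose representative it matches at the identity threshold over at
  least 80% of its own length, otherwise it founds a new cluster. Only
  representatives (the longest member of each cluster) are emitted.

* ``merge_collections`` — reconcile two clusterings of the same underlying
  data: one that removes redundancy aggressively but loses transcripts, and
  one that keeps everything but stays redundant. Secondary transcripts that
  are identical to, or contained in, a primary transcript are replaced by
  their primary counterpart (emitted once); the rest pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import orf as orf_mod
from . import qc
from .seqio import GenomeSequence

MEMBER_COVERAGE = 0.80  # fraction of a member's own length that must align


@dataclass
class ClusterAssignment:
    """Representative id -> member ids, with each member's identity to it."""

    clusters: Dict[str, List[str]] = field(default_factory=dict)
    identities: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def n_clusters(self) -> int:
        return len(self.clusters)


def _comparison_key(rec: GenomeSequence, level: str) -> Optional[GenomeSequence]:
    if level == "dna":
        return rec
    top = orf_mod.longest_orf(rec.sequence) if len(rec.sequence) >= 3 else None
    if top is None or not top.peptide:
        return None
    return GenomeSequence(rec.name, top.peptide)


def dedupe(
    records: Sequence[GenomeSequence],
    level: str = "dna",
    identity_threshold: float = 0.95,
    scoring: qc.Scoring = qc.Scoring(),
) -> Tuple[List[GenomeSequence], ClusterAssignment]:
    """Greedy longest-first redundancy removal.

    At ``level='protein'`` comparisons run on longest-ORF peptides but the
    emitted representatives are the original transcripts. Sequences without
    any ORF cannot be compared at protein level and found their own cluster.
    Representatives are the longest members (ties: lexicographically smallest
    id); output preserves input order.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1.0]")
    if level not in ("dna", "protein"):
        raise ValueError(f"unknown level {level!r}")

    order = sorted(records, key=lambda r: (-len(r.sequence), r.name))
    reps: List[GenomeSequence] = []  # original records, longest-first
    rep_keys: List[Optional[GenomeSequence]] = []
    assignment = ClusterAssignment()

    for rec in order:
        key = _comparison_key(rec, level)
        joined = False
        if key is not None:
            for rep, rep_key in zip(reps, rep_keys):
                if rep_key is None:
                    continue
                hit = qc.align_local(key, rep_key, scoring)
                if (
                    hit.identity >= identity_threshold
                    and hit.query_coverage(len(key.sequence)) >= MEMBER_COVERAGE
                ):
                    assignment.clusters[rep.name].append(rec.name)
                    assignment.identities[(rep.name, rec.name)] = hit.identity
                    joined = True
                    break
        if not joined:
            reps.append(rec)
            rep_keys.append(key)
            assignment.clusters[rec.name] = [rec.name]
            assignment.identities[(rec.name, rec.name)] = 1.0

    rep_names = {r.name for r in reps}
    kept = [r for r in records if r.name in rep_names]
    return kept, assignment


@dataclass
class MergeReport:
    identical_replaced: int = 0
    contained_replaced: int = 0
    secondary_kept: int = 0
    primary_total: int = 0
    primary_used: int = 0
    final_total: int = 0


def merge_collections(
    primary: Sequence[GenomeSequence],
    secondary: Sequence[GenomeSequence],
    identity: float = 0.98,
    containment_cov: float = 0.95,
    min_length: int = 301,
    scoring: qc.Scoring = qc.Scoring(),
) -> Tuple[List[GenomeSequence], MergeReport]:
    """Replace secondary transcripts that match a primary one.

    Each secondary transcript is classified against the primary collection:

    * identical — reciprocal >= ``identity`` over >= ``containment_cov`` of
      *both* lengths;
    * contained — >= ``identity`` over >= ``containment_cov`` of its *own*
      length within a primary transcript;
    * kept — no qualifying match; passes through unchanged.

    Identical/contained transcripts are replaced by their best-scoring
    primary counterpart (ties: smallest primary id), each referenced primary
    emitted once. Transcripts shorter than ``min_length`` are dropped from
    both collections before matching. Output order: referenced primaries
    (primary order), then kept secondaries (secondary order); the final
    count is always primary_used + secondary_kept.
    """
    if not 0.5 < identity <= 1.0 or not 0.5 < containment_cov <= 1.0:
        raise ValueError("thresholds must be in (0.5, 1.0]")

    primary = [p for p in primary if len(p.sequence) >= min_length]
    secondary = [s for s in secondary if len(s.sequence) >= min_length]
    report = MergeReport(primary_total=len(primary))
    used_primary: Dict[str, GenomeSequence] = {}
    kept_secondary: List[GenomeSequence] = []

    for sec in secondary:
        best: Optional[Tuple[int, str, str, GenomeSequence]] = None
        for pri in sorted(primary, key=lambda p: p.name):
            hit = qc.align_local(sec, pri, scoring)
            if hit.identity < identity:
                continue
            sec_cov = hit.query_coverage(len(sec.sequence))
            pri_cov = (hit.t_interval[1] - hit.t_interval[0]) / len(pri.sequence)
            if sec_cov >= containment_cov and pri_cov >= containment_cov:
                cls = "identical"
            elif sec_cov >= containment_cov:
                cls = "contained"
            else:
                continue
            if best is None or hit.score > best[0]:
                best = (hit.score, cls, pri.name, pri)
        if best is None:
            report.secondary_kept += 1
            kept_secondary.append(sec)
        else:
            _, cls, _, pri = best
            if cls == "identical":
                report.identical_replaced += 1
            else:
                report.contained_replaced += 1
            used_primary.setdefault(pri.name, pri)

    out = [p for p in primary if p.name in used_primary] + kept_secondary
    report.primary_used = len(used_primary)
    report.final_total = len(out)
    return out, report
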