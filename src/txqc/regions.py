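"""Unexplained transcribed regions: deep coverage outside known models.

A region qualifies when every base reaches the depth floor (default 50),
no base overlaps an excluded transcript interval, and the run is at least
``min_length`` (default 300 bp) long. Regions are maximal: extending either
end violates depth, masking or chromosome bounds. An excluded interval
splits a qualifying run; each side is tested against ``min_length``
independently. Regions are strandless (coverage tracks carry no strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .seqio import CoverageTrack, TranscriptModel


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    min_depth_observed: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


def models_to_intervals(models: Iterable[TranscriptModel],
                        mode: str = "span") -> List[Tuple[str, int, int]]:
    """Exclusion intervals from transcript models.

    ``mode='span'`` (default) excludes the full genomic span of each model —
    a deep run inside an annotated intron is explained by its transcript.
    ``mode='exons'`` excludes exons only.
    """
    out = []
    for m in models:
        if mode == "span":
            s, e = m.span
            out.append((m.chrom, s, e))
        elif mode == "exons":
            out.extend((m.chrom, s, e) for s, e in m.exons)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def find_unexplained_regions(
    coverage: CoverageTrack,
    exclude_intervals: Sequence[Tuple[str, int, int]] = (),
    min_length: int = 300,
    min_cov: int = 50,
    cov_mode: str = "min-depth",
) -> List[Region]:
    """Maximal unmasked runs satisfying the depth criterion.

    ``cov_mode='min-depth'`` (default): every base in the region must have
    depth >= ``min_cov``. ``cov_mode='mean-depth'``: maximal unmasked runs
    of non-zero depth whose mean depth reaches ``min_cov``. Results sorted
    by (chrom, start).
    """
    if min_length < 1 or min_cov < 1:
        raise ValueError("min_length and min_cov must be >= 1")
    if cov_mode not in ("min-depth", "mean-depth"):
        raise ValueError(f"unknown cov_mode {cov_mode!r}")

    masks: Dict[str, np.ndarray] = {
        chrom: np.zeros(len(coverage[chrom]), dtype=bool)
        for chrom in coverage.chroms()
    }
    for chrom, s, e in exclude_intervals:
        if chrom not in masks:
            raise KeyError(f"excluded chromosome {chrom!r} not in coverage track")
        masks[chrom][max(s, 0):e] = True

    out: List[Region] = []
    for chrom in sorted(coverage.chroms()):
        depth = coverage[chrom]
        if cov_mode == "min-depth":
            ok = (depth >= min_cov) & ~masks[chrom]
        else:
            ok = (depth > 0) & ~masks[chrom]
        for s, e in _runs(ok):
            if e - s < min_length:
                continue
            window = depth[s:e]
            mean = float(window.mean())
            if cov_mode == "mean-depth" and mean < min_cov:
                continue
            out.append(Region(chrom, int(s), int(e), int(window.min()), mean))
    return out


def _runs(flags: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True, as (start, end) half-open pairs."""
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def regions_to_bed(regions: Iterable[Region]) -> List[tuple]:
    return [
        (r.chrom, r.start, r.end, f"depth>={r.min_depth_observed}", round(r.mean_depth))
        for r in regions
    ]
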