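"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a result by direct enumeration / textbook dynamic
programming, sharing no code path with the package implementation.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np
from Bio.Seq import Seq
from numba import njit

STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: Dict[str, str] = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
}


def _translate_codon(codon: str) -> str:
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        return "X"  # contains N: never a stop
    return aa


def brute_force_orfs(seq: str) -> Set[Tuple[str, int, int, str]]:
    """All maximal stop-to-stop ORFs in 6 frames, by direct codon scanning.

    Returns (strand, forward_start, forward_end, peptide) tuples; the
    interval includes the terminal stop codon when present.
    """
    out: Set[Tuple[str, int, int, str]] = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            pos = frame
            run_start = None
            pep: List[str] = []

            def emit(end: int):
                if pep:
                    st, en = run_start, end
                    if strand == "-":
                        st, en = n - en, n - st
                    out.add((strand, st, en, "".join(pep)))

            while pos + 3 <= n:
                aa = _translate_codon(s[pos:pos + 3])
                if aa == "*":
                    emit(pos + 3)  # terminal stop included in the interval
                    pep = []
                    run_start = None
                else:
                    if run_start is None:
                        run_start = pos
                    pep.append(aa)
                pos += 3
            emit(pos)  # sequence end acts as a boundary
    return out


def brute_force_longest(seq: str) -> Tuple[str, int, int, str] | None:
    """Longest ORF under the ordering (aa length desc, '+' first, start asc)."""
    orfs = brute_force_orfs(seq)
    if not orfs:
        return None
    return min(orfs, key=lambda t: (-len(t[3]), t[0] != "+", t[1]))


@njit(cache=True)
def _gotoh_local(a: np.ndarray, b: np.ndarray, match: int, mismatch: int,
                 gap_open: int) -> int:
    """Smith-Waterman with affine gaps (open cost, zero extension)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int64)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1])
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j])
            sub = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + sub
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def dp_local_score(query: str, target: str, match: int = 1, mismatch: int = -1,
                   gap_open: int = 1) -> int:
    a = np.frombuffer(query.encode(), dtype=np.uint8)
    b = np.frombuffer(target.encode(), dtype=np.uint8)
    return int(_gotoh_local(a, b, match, mismatch, gap_open))


def brute_force_regions(depth: np.ndarray, masked: np.ndarray,
                        min_length: int, min_cov: int) -> List[Tuple[int, int]]:
    """Base-by-base scan for maximal qualifying runs."""
    regions = []
    start = None
    for i in range(len(depth) + 1):
        ok = i < len(depth) and depth[i] >= min_cov and not masked[i]
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_length:
                regions.append((start, i))
            start = None
    return regions


def paint_coverage(length: int, records: List[Tuple[int, int, int]]) -> np.ndarray:
    """Record-by-record, base-by-base painting of a depth vector."""
    depth = np.zeros(length, dtype=np.int64)
    for start, end, d in records:
        for i in range(start, end):
            depth[i] = d
    return depth
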