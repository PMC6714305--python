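"""Bisulfite-asymmetric pairwise alignment of amplicon reads.

Reads are aligned globally against the *unconverted* genomic reference under
an asymmetric substitution rule: a reference C aligned to a read T scores as a
match (the expected bisulfite conversion), and a reference C aligned to a read
C also scores as a match (a methylated or unconverted cytosine). Methylation
state therefore never influences the alignment score, which keeps downstream
M/U calling unbiased. All other mismatches are penalized.

End gaps toward the read's ends are free: the read must be consumed in full,
but reference overhang before the first or after the last read base costs
nothing (standard semi-global alignment for an amplicon read inside its
reference window).

Both the read and its reverse complement are aligned; the reverse complement
is scored under the same C~T-tolerant rule against the top strand, which is
the mirror image of scoring the original read letters against the bottom
strand's G~A conversion expectation. The higher-scoring orientation wins, ties
going to forward. Within the dynamic program, ties break diagonal > up > left.

The full dynamic program is quadratic; an optional diagonal band accelerates
the high-throughput path for substitution-only amplicon reads (band=None
retains the exact full-matrix contract).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_A, _C, _G, _T, _N = 0, 1, 2, 3, 4

_ENCODE_LUT = np.full(256, _N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = np.array([_T, _G, _C, _A, _N], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch) or self.gap >= 0:
            raise ValueError("require match > 0 > mismatch and gap < 0")


@dataclass
class Alignment:
    """Result of aligning one read against one locus reference."""

    score: int
    orientation: str  # "forward" | "reverse-complement"
    ref_to_read: np.ndarray  # per reference position: read index or -1
    aligned_read: str  # the sequence that was aligned (revcomp'd if reverse)
    locus_name: str


@njit(cache=True)
def _semi_global(read, ref, match, mismatch, gap, band):  # pragma: no cover
    m = read.size
    n = ref.size
    NEG = -(1 << 30)
    D = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    for j in range(n + 1):
        D[0, j] = 0  # free leading reference overhang
    for i in range(1, m + 1):
        lo = 1
        hi = n
        if band > 0:
            lo = i - band
            if lo < 1:
                lo = 1
            hi = i + band
            if hi > n:
                hi = n
        if lo == 1 and (band <= 0 or i <= band):
            D[i, 0] = D[i - 1, 0] + gap
        for j in range(lo, hi + 1):
            r = ref[j - 1]
            q = read[i - 1]
            if (q == r and q < 4) or (r == _C and q == _T):
                s = match
            else:
                s = mismatch
            best = D[i - 1, j - 1] + s
            up = D[i - 1, j] + gap
            if up > best:
                best = up
            left = D[i, j - 1] + gap
            if left > best:
                best = left
            D[i, j] = best
    best = D[m, n]
    jend = n
    for j in range(n - 1, -1, -1):
        if D[m, j] > best:  # strict: keep the largest maximizer
            best = D[m, j]
            jend = j
    # traceback with diagonal > up > left tie-breaking
    ref2read = np.full(n, -1, dtype=np.int64)
    i = m
    j = jend
    while i > 0:
        if j > 0:
            r = ref[j - 1]
            q = read[i - 1]
            if (q == r and q < 4) or (r == _C and q == _T):
                s = match
            else:
                s = mismatch
            if D[i, j] == D[i - 1, j - 1] + s:
                ref2read[j - 1] = i - 1
                i -= 1
                j -= 1
                continue
        if D[i, j] == D[i - 1, j] + gap:
            i -= 1
            continue
        j -= 1
    return best, ref2read


def align_bisulfite(
    read: str,
    locus,
    scoring: Scoring = Scoring(),
    band: int | None = None,
) -> Alignment:
    """Align a read (both orientations) against a locus reference."""
    if not read:
        raise ValueError("empty read")
    ref_codes = encode_seq(locus.reference)
    fwd = read.upper()
    rev = revcomp(fwd)
    b = 0 if band is None else int(band)
    s_f, map_f = _semi_global(
        encode_seq(fwd), ref_codes, scoring.match, scoring.mismatch, scoring.gap, b
    )
    s_r, map_r = _semi_global(
        encode_seq(rev), ref_codes, scoring.match, scoring.mismatch, scoring.gap, b
    )
    if s_f >= s_r:  # ties break toward forward
        return Alignment(int(s_f), "forward", map_f, fwd, locus.name)
    return Alignment(int(s_r), "reverse-complement", map_r, rev, locus.name)
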