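"""String-matching kernels for read classification.

Three primitives drive the classifier:

* Hamming-distance barcode lookup with ambiguity rejection — a read is
  assigned to a barcode only when a unique set member is closest within the
  allowed mismatch radius; ties at the minimal distance are rejected as
  ambiguous rather than guessed.
* The restricted Damerau–Levenshtein distance (optimal string alignment,
  OSA) for validating adapter and flank segments: unit-cost substitutions,
  insertions, deletions, and adjacent transpositions, with the restriction
  that no substring is edited twice.
* Needleman–Wunsch global alignment with linear gap costs, used to detect
  the terminal overhang that a small indel leaves when the left flank is
  aligned to its expected read window (read rescue).

``N`` bases in reads never match anything (they count as mismatches under
both metrics); library sequences are N-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

__all__ = [
    "hamming_distance",
    "dl_distance",
    "BarcodeIndex",
    "LookupStatus",
    "BarcodeLookup",
    "AlignmentResult",
    "needleman_wunsch",
]


def hamming_distance(a: str, b: str) -> int:
    """Positions at which *a* and *b* differ; N mismatches every base."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if a == b and "N" not in a:
        return 0
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def dl_distance(a: str, b: str, cutoff: int | None = None) -> int:
    """Restricted Damerau–Levenshtein (optimal string alignment) distance.

    Unit costs for substitution, insertion, deletion, and adjacent
    transposition; no substring is edited more than once, so e.g.
    ``dl_distance("CA", "ABC") == 3`` (the unrestricted variant gives 2).

    With ``cutoff`` set, any distance exceeding it is reported as
    ``cutoff + 1`` and the computation may stop early (used on the demux
    hot path where only "within budget?" matters).
    """
    la, lb = len(a), len(b)
    cap = None if cutoff is None else cutoff + 1
    if cap is not None and abs(la - lb) >= cap:
        return cap
    if a == b and "N" not in a:
        return 0
    # fast path: equal-length, Hamming 1 implies OSA distance exactly 1
    if la == lb:
        h = hamming_distance(a, b)
        if h <= 1:
            return h
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        ca = a[i - 1]
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cb = b[j - 1]
            eq = ca == cb and ca != "N"
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (0 if eq else 1))
            if (prev2 is not None and j > 1 and not eq
                    and ca == b[j - 2] and a[i - 2] == cb
                    and ca != "N" and a[i - 2] != "N"):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if cap is not None and min(cur) >= cap:
            return cap
        prev2, prev = prev, cur
    dist = prev[lb]
    return dist if cap is None else min(dist, cap)


class LookupStatus(Enum):
    ASSIGNED = "assigned"
    NO_MATCH = "no_match"
    AMBIGUOUS = "ambiguous"


class BarcodeLookup(NamedTuple):
    status: LookupStatus
    index: int | None
    distance: int | None


class BarcodeIndex:
    """Hash-backed barcode lookup with a Hamming mismatch radius.

    An exact dictionary hit (distance 0) always wins.  For ``max_mismatch=1``
    the query's single-base neighbors are probed against the same dictionary
    — behaviorally identical to scanning the whole set, but O(4L) per query
    instead of O(set size).  Larger radii fall back to a full scan.  A query
    is assigned only when one member is uniquely closest within the radius;
    two or more members at the same minimal distance yield ``AMBIGUOUS``.
    """

    _ALPHABET = "ACGT"

    def __init__(self, barcodes, max_mismatch: int = 0):
        barcodes = list(barcodes)
        if not barcodes:
            raise ValueError("empty barcode set")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError(f"unequal barcode lengths {sorted(lengths)}")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in set")
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.barcodes = barcodes
        self.barcode_length = lengths.pop()
        self.max_mismatch = max_mismatch
        self.table = {b: i for i, b in enumerate(barcodes)}

    def lookup(self, query: str) -> BarcodeLookup:
        if len(query) != self.barcode_length:
            raise ValueError(
                f"query length {len(query)} != barcode length {self.barcode_length}")
        hit = self.table.get(query)
        if hit is not None and "N" not in query:
            return BarcodeLookup(LookupStatus.ASSIGNED, hit, 0)
        if self.max_mismatch == 0:
            return BarcodeLookup(LookupStatus.NO_MATCH, None, None)
        if self.max_mismatch == 1:
            hits = set()
            for pos, base in enumerate(query):
                prefix, suffix = query[:pos], query[pos + 1:]
                for alt in self._ALPHABET:
                    if alt == base:
                        continue
                    idx = self.table.get(prefix + alt + suffix)
                    if idx is not None:
                        hits.add(idx)
            if not hits:
                return BarcodeLookup(LookupStatus.NO_MATCH, None, None)
            if len(hits) == 1:
                return BarcodeLookup(LookupStatus.ASSIGNED, hits.pop(), 1)
            return BarcodeLookup(LookupStatus.AMBIGUOUS, None, 1)
        # radius >= 2: scan the set
        best, best_idx, ties = None, None, 0
        for i, bc in enumerate(self.barcodes):
            d = hamming_distance(query, bc)
            if d > self.max_mismatch:
                continue
            if best is None or d < best:
                best, best_idx, ties = d, i, 1
            elif d == best:
                ties += 1
        if best is None:
            return BarcodeLookup(LookupStatus.NO_MATCH, None, None)
        if ties > 1:
            return BarcodeLookup(LookupStatus.AMBIGUOUS, None, best)
        return BarcodeLookup(LookupStatus.ASSIGNED, best_idx, best)


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment plus the signed terminal overhang.

    ``overhang_length`` measures how many query bases the reference-aligned
    block consumes beyond (``+``, net insertion in the query) or short of
    (``-``, net deletion) the reference length, after discounting terminal
    gaps.  A query that is just the reference with one inserted base has
    overhang +1; with one deleted base, −1.
    """

    aligned_ref: str
    aligned_query: str
    score: int
    overhang_length: int


def needleman_wunsch(reference: str, query: str,
                     match: int = 1, mismatch: int = -1,
                     gap: int = -1) -> AlignmentResult:
    """Optimal global alignment with linear gap penalties.

    Traceback tie-break is fixed (diagonal > up > left, "up" consuming a
    reference base) so results are deterministic.  ``N`` scores as a
    mismatch against everything.
    """
    if not reference or not query:
        raise ValueError("sequences must be non-empty")
    n, m = len(reference), len(query)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        ri = reference[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            qj = query[j - 1]
            sub = match if (ri == qj and ri != "N") else mismatch
            row[j] = max(prev[j - 1] + sub, prev[j] + gap, row[j - 1] + gap)
    # deterministic traceback: diagonal > up > left
    i, j = n, m
    ref_out: list[str] = []
    qry_out: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            ri, qj = reference[i - 1], query[j - 1]
            sub = match if (ri == qj and ri != "N") else mismatch
            if score[i][j] == score[i - 1][j - 1] + sub:
                ref_out.append(ri)
                qry_out.append(qj)
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + gap:
            ref_out.append(reference[i - 1])
            qry_out.append("-")
            i -= 1
            continue
        ref_out.append("-")
        qry_out.append(query[j - 1])
        j -= 1
    aligned_ref = "".join(reversed(ref_out))
    aligned_query = "".join(reversed(qry_out))
    trail_ref_gaps = len(aligned_ref) - len(aligned_ref.rstrip("-"))
    trail_qry_gaps = len(aligned_query) - len(aligned_query.rstrip("-"))
    overhang = (m - trail_ref_gaps) - (n - trail_qry_gaps)
    return AlignmentResult(aligned_ref, aligned_query, score[n][m], overhang)
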