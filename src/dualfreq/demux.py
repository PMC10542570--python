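"""Read-pair classification: demultiplexing, filtering, genotyping, rescue.

Each read pair is pushed through a fixed decision ladder:

1. **Barcodes.**  The barcode span of each mate is looked up in its set's
   :class:`~dualfreq.matching.BarcodeIndex`.  A missing or ambiguous hit on
   either mate rejects the pair (``barcode_no_match`` / ``barcode_ambiguous``).
2. **Constant segments.**  The restricted Damerau–Levenshtein distance is
   computed for adapter 1 and the left flank on read 1, and adapter 2 and the
   right flank on read 2.  The SUM of the four distances is the pair's edit
   cost; exceeding the configured budget rejects the pair (``edit_budget``).
3. **Genotype.**  The allele span of read 1 is compared exactly against the
   library's allele sequences; a hit is a ``valid`` read.
4. **Rescue.**  If no allele matches and rescue is enabled, the left flank is
   globally aligned (Needleman–Wunsch) to its read window extended by
   ``max_shift`` bases; a terminal overhang of k (0 < |k| <= max_shift)
   indicates a small indel, the allele span is re-extracted shifted by k, and
   a hit is recorded as ``rescued``.  Otherwise: ``allele_unrecognized``.

Reads too short for their anatomy are tallied as ``malformed``.  Every pair
lands in exactly one bin, so counts + reject tallies == total pairs.

Read anatomy is explicit configuration: by default barcode 1 starts read 1,
followed by adapter 1, the left flank and the allele; barcode 2 starts read
2, followed by adapter 2 and the right flank.  Read 2 segments are compared
in sequencing orientation against the reverse complement of the amplicon-
orientation flank, which is equivalent to reverse-complementing the mate
before span extraction.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_spec import LibrarySpec, enumerate_pairs
from .matching import (BarcodeIndex, LookupStatus, dl_distance,
                       needleman_wunsch)

__all__ = [
    "Span",
    "MateAnatomy",
    "ReadAnatomy",
    "DemuxParams",
    "ReadClassification",
    "AlleleCountTable",
    "Demultiplexer",
    "classify_read_pair",
    "rescue_read",
    "demultiplex",
    "write_counts_tsv",
    "write_rejects_tsv",
    "read_counts_tsv",
    "VALID",
    "RESCUED",
    "REJECT_CATEGORIES",
]

VALID = "valid"
RESCUED = "rescued"
REJECT_BARCODE_NO_MATCH = "barcode_no_match"
REJECT_BARCODE_AMBIGUOUS = "barcode_ambiguous"
REJECT_EDIT_BUDGET = "edit_budget"
REJECT_ALLELE = "allele_unrecognized"
MALFORMED = "malformed"

REJECT_CATEGORIES = (REJECT_BARCODE_NO_MATCH, REJECT_BARCODE_AMBIGUOUS,
                     REJECT_EDIT_BUDGET, REJECT_ALLELE, MALFORMED)

Span = tuple[int, int]


@dataclass(frozen=True)
class MateAnatomy:
    """Contiguous spans (5'-measured, sequencing orientation) within one mate."""

    barcode: Span
    adapter: Span
    flank: Span
    allele: Span | None = None

    @property
    def min_length(self) -> int:
        end = self.flank[1]
        if self.allele is not None:
            end = max(end, self.allele[1])
        return end


@dataclass(frozen=True)
class ReadAnatomy:
    """Where each segment sits in the two mates of a pair."""

    r1: MateAnatomy
    r2: MateAnatomy

    @classmethod
    def from_spec(cls, spec: LibrarySpec) -> "ReadAnatomy":
        """Default layout: bc + adapter + flank (+ allele on read 1), contiguous."""
        l1 = spec.barcode1_length
        a1 = len(spec.adapter1)
        fl = len(spec.flank_left)
        al = spec.allele_length
        r1 = MateAnatomy(barcode=(0, l1), adapter=(l1, l1 + a1),
                         flank=(l1 + a1, l1 + a1 + fl),
                         allele=(l1 + a1 + fl, l1 + a1 + fl + al))
        l2 = spec.barcode2_length
        a2 = len(spec.adapter2)
        fr = len(spec.flank_right)
        r2 = MateAnatomy(barcode=(0, l2), adapter=(l2, l2 + a2),
                         flank=(l2 + a2, l2 + a2 + fr))
        return cls(r1=r1, r2=r2)


@dataclass(frozen=True)
class DemuxParams:
    """Classification thresholds.

    ``edit_budget`` caps the summed Damerau–Levenshtein distance over the
    four constant segments of a pair (default 4, the standard operating
    point together with ``barcode_mismatch=0``).  ``per_segment_budget``
    optionally switches the budget to apply to each segment separately.
    """

    barcode_mismatch: int = 0
    edit_budget: int = 4
    rescue: bool = True
    max_shift: int = 3
    per_segment_budget: bool = False


@dataclass
class ReadClassification:
    """Fate of one read pair."""

    read_id: str
    verdict: str
    barcode_pair: tuple[int, int] | None = None
    allele: str | None = None
    edit_cost: int | None = None
    rescue_shift: int | None = None


@dataclass
class AlleleCountTable:
    """Per-pair, per-allele read counts plus reject tallies.

    Invariant: ``total_reads == sum(counts.values()) + sum(reject_tallies.values())``
    and ``sum(counts.values()) == n_valid + n_rescued``.
    """

    counts: dict[tuple[int, int, str], int] = field(default_factory=dict)
    reject_tallies: dict[str, int] = field(default_factory=dict)
    n_valid: int = 0
    n_rescued: int = 0
    total_reads: int = 0

    def add(self, c: ReadClassification) -> None:
        self.total_reads += 1
        if c.verdict in (VALID, RESCUED):
            i1, i2 = c.barcode_pair
            key = (i1, i2, c.allele)
            self.counts[key] = self.counts.get(key, 0) + 1
            if c.verdict == VALID:
                self.n_valid += 1
            else:
                self.n_rescued += 1
        else:
            self.reject_tallies[c.verdict] = self.reject_tallies.get(c.verdict, 0) + 1

    def pair_total(self, pair: tuple[int, int]) -> int:
        i1, i2 = pair
        return sum(n for (a, b, _), n in self.counts.items() if (a, b) == (i1, i2))

    def check_conservation(self) -> bool:
        return self.total_reads == (sum(self.counts.values())
                                    + sum(self.reject_tallies.values()))


class Demultiplexer:
    """Reusable classifier: precomputed indexes and segment references."""

    def __init__(self, spec: LibrarySpec, anatomy: ReadAnatomy | None = None,
                 params: DemuxParams | None = None):
        self.spec = spec
        self.anatomy = anatomy or ReadAnatomy.from_spec(spec)
        self.params = params or DemuxParams()
        self.index1 = BarcodeIndex(spec.barcodes1, self.params.barcode_mismatch)
        self.index2 = BarcodeIndex(spec.barcodes2, self.params.barcode_mismatch)
        self._alleles_by_seq = {seq: label for label, seq in spec.alleles.items()}
        self._allele_len = spec.allele_length
        self._flank_right_rc = reverse_complement(spec.flank_right)
        # (segment extracted from, span, reference) for the shared edit budget
        a = self.anatomy
        self._segments = (
            ("r1", a.r1.adapter, spec.adapter1),
            ("r1", a.r1.flank, spec.flank_left),
            ("r2", a.r2.adapter, spec.adapter2),
            ("r2", a.r2.flank, self._flank_right_rc),
        )

    def classify(self, read_id: str, r1: str, r2: str) -> ReadClassification:
        a = self.anatomy
        p = self.params
        if len(r1) < a.r1.min_length or len(r2) < a.r2.min_length:
            return ReadClassification(read_id, MALFORMED)
        hit1 = self.index1.lookup(r1[a.r1.barcode[0]:a.r1.barcode[1]])
        if hit1.status is not LookupStatus.ASSIGNED:
            verdict = (REJECT_BARCODE_AMBIGUOUS
                       if hit1.status is LookupStatus.AMBIGUOUS
                       else REJECT_BARCODE_NO_MATCH)
            return ReadClassification(read_id, verdict)
        hit2 = self.index2.lookup(r2[a.r2.barcode[0]:a.r2.barcode[1]])
        if hit2.status is not LookupStatus.ASSIGNED:
            verdict = (REJECT_BARCODE_AMBIGUOUS
                       if hit2.status is LookupStatus.AMBIGUOUS
                       else REJECT_BARCODE_NO_MATCH)
            return ReadClassification(read_id, verdict)
        pair = (hit1.index, hit2.index)

        budget = p.edit_budget
        cutoff = budget  # distances above budget need not be resolved exactly
        cost = 0
        for mate, (s, e), ref in self._segments:
            seg = (r1 if mate == "r1" else r2)[s:e]
            d = dl_distance(seg, ref, cutoff=cutoff)
            if p.per_segment_budget:
                if d > budget:
                    return ReadClassification(read_id, REJECT_EDIT_BUDGET,
                                              barcode_pair=pair, edit_cost=d)
                cost = max(cost, d)
            else:
                cost += d
                if cost > budget:
                    return ReadClassification(read_id, REJECT_EDIT_BUDGET,
                                              barcode_pair=pair, edit_cost=cost)

        s, e = a.r1.allele
        label = self._alleles_by_seq.get(r1[s:e])
        if label is not None:
            return ReadClassification(read_id, VALID, barcode_pair=pair,
                                      allele=label, edit_cost=cost)
        if p.rescue:
            rescued = self.rescue(r1)
            if rescued is not None:
                label, shift = rescued
                return ReadClassification(read_id, RESCUED, barcode_pair=pair,
                                          allele=label, edit_cost=cost,
                                          rescue_shift=shift)
        return ReadClassification(read_id, REJECT_ALLELE, barcode_pair=pair,
                                  edit_cost=cost)

    def rescue(self, r1: str) -> tuple[str, int] | None:
        """Indel rescue via left-flank alignment and allele re-extraction.

        The left flank (reference) is aligned to its read window extended by
        ``max_shift`` bases; the alignment's terminal overhang gives the net
        indel shift k.  For 0 < |k| <= max_shift the allele span is re-read
        at its shifted position and re-queried exactly.

        When the indel sits in the last base or two of the flank, the
        alignment has almost no downstream anchor and the overhang can be
        wrong; the remaining shifts within ``max_shift`` are then probed
        directly, and a rescue is accepted only when the probed shifts agree
        on a single allele label (an exact allele hit at a wrong shift would
        require a chance k-mer collision).
        """
        a = self.anatomy
        max_shift = self.params.max_shift
        fs, fe = a.r1.flank
        window = r1[fs:fe + max_shift]
        if len(window) < 2:
            return None
        aln = needleman_wunsch(self.spec.flank_left, window)
        k = aln.overhang_length

        shifts: list[int] = []
        if 0 < abs(k) <= max_shift:
            shifts.append(k)
        for step in range(1, max_shift + 1):
            for cand in (step, -step):
                if cand != 0 and cand not in shifts:
                    shifts.append(cand)

        s, e = a.r1.allele
        hits: list[tuple[str, int]] = []
        for shift in shifts:
            if s + shift < 0:
                continue
            seg = r1[s + shift:e + shift]
            if len(seg) != self._allele_len:
                continue
            label = self._alleles_by_seq.get(seg)
            if label is not None:
                hits.append((label, shift))
        if not hits:
            return None
        labels = {label for label, _ in hits}
        if len(labels) > 1:
            return None  # conflicting genotypes across shifts: too ambiguous
        return hits[0]


def classify_read_pair(r1: str, r2: str, spec: LibrarySpec,
                       anatomy: ReadAnatomy | None = None,
                       params: DemuxParams | None = None,
                       read_id: str = "read") -> ReadClassification:
    """One-shot wrapper around :class:`Demultiplexer.classify`."""
    return Demultiplexer(spec, anatomy, params).classify(read_id, r1, r2)


def rescue_read(r1: str, spec: LibrarySpec,
                anatomy: ReadAnatomy | None = None,
                max_shift: int = 3) -> tuple[str, int] | None:
    """One-shot wrapper around :class:`Demultiplexer.rescue`."""
    dm = Demultiplexer(spec, anatomy, DemuxParams(max_shift=max_shift))
    return dm.rescue(r1)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


class PairedFastqError(RuntimeError):
    """Mate files are desynchronized or unreadable."""


def _id_token(title: str) -> str:
    token = title.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def demultiplex(fastq_r1: str | Path, fastq_r2: str | Path, spec: LibrarySpec,
                anatomy: ReadAnatomy | None = None,
                params: DemuxParams | None = None,
                classifications_out: str | Path | None = None) -> AlleleCountTable:
    """Classify every pair of a paired FASTQ (plain or gzip) into counts.

    Mates must be synchronized (same order and count); a mismatch is a hard
    error.  ``classifications_out`` optionally streams a per-read TSV.
    """
    dm = Demultiplexer(spec, anatomy, params)
    table = AlleleCountTable()
    sentinel = object()
    out = open(classifications_out, "w") if classifications_out else None
    try:
        if out:
            out.write("read_id\tverdict\tbc1\tbc2\tallele\tedit_cost\trescue_shift\n")
        with _open_text(fastq_r1) as f1, _open_text(fastq_r2) as f2:
            it = itertools.zip_longest(FastqGeneralIterator(f1),
                                       FastqGeneralIterator(f2),
                                       fillvalue=sentinel)
            for rec1, rec2 in it:
                if rec1 is sentinel or rec2 is sentinel:
                    raise PairedFastqError("mate files have different read counts")
                title1, seq1, _ = rec1
                title2, seq2, _ = rec2
                rid = _id_token(title1)
                if rid != _id_token(title2):
                    raise PairedFastqError(
                        f"desynchronized mates: {title1!r} vs {title2!r}")
                c = dm.classify(rid, seq1, seq2)
                table.add(c)
                if out:
                    i1 = "" if c.barcode_pair is None else c.barcode_pair[0]
                    i2 = "" if c.barcode_pair is None else c.barcode_pair[1]
                    out.write(f"{c.read_id}\t{c.verdict}\t{i1}\t{i2}\t"
                              f"{c.allele or ''}\t"
                              f"{'' if c.edit_cost is None else c.edit_cost}\t"
                              f"{'' if c.rescue_shift is None else c.rescue_shift}\n")
    finally:
        if out:
            out.close()
    return table


def write_counts_tsv(table: AlleleCountTable, spec: LibrarySpec,
                     path: str | Path) -> None:
    """Counts TSV in deterministic order: pair enumeration, then allele order."""
    rows = []
    for i1, i2 in enumerate_pairs(spec):
        for label in spec.allele_labels:
            rows.append((spec.barcode1_names[i1], spec.barcode2_names[i2],
                         label, table.counts.get((i1, i2, label), 0)))
    pd.DataFrame(rows, columns=["bc1_name", "bc2_name", "allele", "count"]) \
        .to_csv(path, sep="\t", index=False)


def write_rejects_tsv(table: AlleleCountTable, path: str | Path) -> None:
    rows = [("valid", table.n_valid), ("rescued", table.n_rescued)]
    rows += [(cat, table.reject_tallies.get(cat, 0)) for cat in REJECT_CATEGORIES]
    rows.append(("total", table.total_reads))
    pd.DataFrame(rows, columns=["category", "count"]) \
        .to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, spec: LibrarySpec) -> AlleleCountTable:
    """Rebuild an :class:`AlleleCountTable` from a counts TSV (rejects lost)."""
    df = pd.read_csv(path, sep="\t", dtype={"count": int})
    idx1 = {n: i for i, n in enumerate(spec.barcode1_names)}
    idx2 = {n: i for i, n in enumerate(spec.barcode2_names)}
    table = AlleleCountTable()
    for _, row in df.iterrows():
        n = int(row["count"])
        if n:
            key = (idx1[row["bc1_name"]], idx2[row["bc2_name"]], row["allele"])
            table.counts[key] = table.counts.get(key, 0) + n
    table.n_valid = sum(table.counts.values())
    table.total_reads = table.n_valid
    return table
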