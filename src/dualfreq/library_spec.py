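"""Library definition: barcodes, adapters, allele flanks, and alleles.

A dual-barcoded amplicon library tags every sample with a unique pair of
barcodes — one drawn from each of two independent sets of up to 48 — so the
number of addressable samples scales as the product of the set sizes (up to
2,304 for 48 x 48).  Every downstream step (read classification, counting,
frequency estimation) consumes the :class:`LibrarySpec` parsed here.

The on-disk format is a FASTA dialect with role-tagged headers::

    >bc1:NAME        a barcode from set 1 (one record per barcode)
    >bc2:NAME        a barcode from set 2
    >adapter1        constant region adjacent to barcode 1 (one record)
    >adapter2        constant region adjacent to barcode 2
    >flank_left      constant sequence 5' of the allele position
    >flank_right     constant sequence 3' of the allele position
    >allele:LABEL    an allele sequence at the target locus

Barcode index order is file order; names are cosmetic.  An optional
two-column-plus TSV (``bc1_name``, ``bc2_name``, ``sample_name``) declares
which barcode pairs were actually used in an experiment; this affects QC
classification only, never counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LibrarySpec",
    "LibrarySpecError",
    "MAX_PAIRS",
    "read_library_spec",
    "write_library_spec",
    "enumerate_pairs",
    "read_used_pairs",
]

#: Hard cap on the pair grid: two sets of 48 barcodes.
MAX_PAIRS = 2304

_DNA_ALPHABET = frozenset("ACGT")


class LibrarySpecError(ValueError):
    """A library specification file violates the format or its invariants."""


@dataclass(frozen=True)
class LibrarySpec:
    """Validated description of a dual-barcoded amplicon library.

    Attributes
    ----------
    barcodes1, barcodes2:
        Ordered barcode sets; index order is definition order.
    adapter1, adapter2:
        Constant regions adjacent to barcode 1 (read 1 orientation) and
        barcode 2 (read 2 orientation).
    flank_left, flank_right:
        Constant sequences immediately 5' and 3' of the polymorphic allele
        position, in amplicon (read 1) orientation.
    alleles:
        Mapping of allele label -> sequence; labels in definition order.
    barcode1_names, barcode2_names:
        Cosmetic names parallel to the barcode lists.
    used_pairs:
        Optional set of (index1, index2) pairs expected in the experiment.
    """

    barcodes1: tuple[str, ...]
    barcodes2: tuple[str, ...]
    adapter1: str
    adapter2: str
    flank_left: str
    flank_right: str
    alleles: dict[str, str]
    barcode1_names: tuple[str, ...] = ()
    barcode2_names: tuple[str, ...] = ()
    used_pairs: frozenset[tuple[int, int]] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", dict(self.alleles))
        if not self.barcode1_names:
            object.__setattr__(
                self, "barcode1_names",
                tuple(f"bc1_{i:02d}" for i in range(len(self.barcodes1))))
        if not self.barcode2_names:
            object.__setattr__(
                self, "barcode2_names",
                tuple(f"bc2_{i:02d}" for i in range(len(self.barcodes2))))
        self._validate()

    def _validate(self) -> None:
        for role, seqs in (("bc1", self.barcodes1), ("bc2", self.barcodes2)):
            if not seqs:
                raise LibrarySpecError(f"barcode set {role!r} is empty")
            lengths = {len(s) for s in seqs}
            if len(lengths) != 1:
                raise LibrarySpecError(
                    f"barcode set {role!r} has unequal lengths {sorted(lengths)}")
            seen: dict[str, int] = {}
            for i, s in enumerate(seqs):
                _check_dna(s, f"{role}[{i}]")
                if s in seen:
                    raise LibrarySpecError(
                        f"duplicate barcode in set {role!r}: "
                        f"record {i} repeats record {seen[s]} ({s})")
                seen[s] = i
        for role, seq in (("adapter1", self.adapter1), ("adapter2", self.adapter2),
                          ("flank_left", self.flank_left),
                          ("flank_right", self.flank_right)):
            _check_dna(seq, role)
        if not self.alleles:
            raise LibrarySpecError("no allele records")
        allele_lengths = set()
        seen_alleles: dict[str, str] = {}
        for label, seq in self.alleles.items():
            _check_dna(seq, f"allele:{label}")
            allele_lengths.add(len(seq))
            if seq in seen_alleles:
                raise LibrarySpecError(
                    f"alleles {seen_alleles[seq]!r} and {label!r} share sequence {seq}")
            seen_alleles[seq] = label
        if len(allele_lengths) != 1:
            raise LibrarySpecError(
                f"allele sequences have unequal lengths {sorted(allele_lengths)}")
        if len(self.barcodes1) * len(self.barcodes2) > MAX_PAIRS:
            raise LibrarySpecError(
                f"{len(self.barcodes1)} x {len(self.barcodes2)} barcode pairs "
                f"exceed the {MAX_PAIRS} maximum")
        if len(self.barcode1_names) != len(self.barcodes1):
            raise LibrarySpecError("barcode1_names length mismatch")
        if len(self.barcode2_names) != len(self.barcodes2):
            raise LibrarySpecError("barcode2_names length mismatch")
        if self.used_pairs is not None:
            for i1, i2 in self.used_pairs:
                if not (0 <= i1 < len(self.barcodes1) and 0 <= i2 < len(self.barcodes2)):
                    raise LibrarySpecError(f"used pair ({i1}, {i2}) out of range")

    # -- convenience accessors -------------------------------------------------

    @property
    def barcode1_length(self) -> int:
        return len(self.barcodes1[0])

    @property
    def barcode2_length(self) -> int:
        return len(self.barcodes2[0])

    @property
    def allele_length(self) -> int:
        return len(next(iter(self.alleles.values())))

    @property
    def allele_labels(self) -> tuple[str, ...]:
        return tuple(self.alleles)

    def pair_name(self, pair: tuple[int, int]) -> tuple[str, str]:
        return self.barcode1_names[pair[0]], self.barcode2_names[pair[1]]

    def with_used_pairs(self, pairs) -> "LibrarySpec":
        return LibrarySpec(
            barcodes1=self.barcodes1, barcodes2=self.barcodes2,
            adapter1=self.adapter1, adapter2=self.adapter2,
            flank_left=self.flank_left, flank_right=self.flank_right,
            alleles=self.alleles,
            barcode1_names=self.barcode1_names, barcode2_names=self.barcode2_names,
            used_pairs=frozenset(tuple(p) for p in pairs))


def _check_dna(seq: str, where: str) -> None:
    if not seq:
        raise LibrarySpecError(f"empty sequence in record {where}")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise LibrarySpecError(
            f"non-ACGT character(s) {sorted(bad)} in record {where}")


def read_library_spec(path: str | Path) -> LibrarySpec:
    """Parse and validate a library FASTA (role-tagged header dialect)."""
    path = Path(path)
    barcodes1: list[str] = []
    barcodes2: list[str] = []
    names1: list[str] = []
    names2: list[str] = []
    singletons: dict[str, str] = {}
    alleles: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        seq = str(record.seq).upper()
        role, _, name = header.partition(":")
        if role == "bc1":
            barcodes1.append(seq)
            names1.append(name or f"bc1_{len(barcodes1) - 1:02d}")
        elif role == "bc2":
            barcodes2.append(seq)
            names2.append(name or f"bc2_{len(barcodes2) - 1:02d}")
        elif role == "allele":
            if not name:
                raise LibrarySpecError(f"allele record {header!r} lacks a label")
            if name in alleles:
                raise LibrarySpecError(f"duplicate allele label {name!r}")
            alleles[name] = seq
        elif role in ("adapter1", "adapter2", "flank_left", "flank_right"):
            if role in singletons:
                raise LibrarySpecError(f"duplicate {role!r} record")
            singletons[role] = seq
        else:
            raise LibrarySpecError(f"unrecognized record header {header!r}")
    missing = [r for r in ("adapter1", "adapter2", "flank_left", "flank_right")
               if r not in singletons]
    if missing:
        raise LibrarySpecError(f"missing role(s): {', '.join(missing)}")
    if not barcodes1 or not barcodes2:
        raise LibrarySpecError("both barcode sets (bc1:/bc2: records) are required")
    if not alleles:
        raise LibrarySpecError("at least one allele: record is required")
    return LibrarySpec(
        barcodes1=tuple(barcodes1), barcodes2=tuple(barcodes2),
        adapter1=singletons["adapter1"], adapter2=singletons["adapter2"],
        flank_left=singletons["flank_left"], flank_right=singletons["flank_right"],
        alleles=alleles,
        barcode1_names=tuple(names1), barcode2_names=tuple(names2))


def write_library_spec(spec: LibrarySpec, path: str | Path) -> None:
    """Write a :class:`LibrarySpec` in the role-tagged FASTA dialect."""
    records = []
    for name, seq in zip(spec.barcode1_names, spec.barcodes1):
        records.append(SeqRecord(Seq(seq), id=f"bc1:{name}", description=""))
    for name, seq in zip(spec.barcode2_names, spec.barcodes2):
        records.append(SeqRecord(Seq(seq), id=f"bc2:{name}", description=""))
    for role in ("adapter1", "adapter2", "flank_left", "flank_right"):
        records.append(SeqRecord(Seq(getattr(spec, role)), id=role, description=""))
    for label, seq in spec.alleles.items():
        records.append(SeqRecord(Seq(seq), id=f"allele:{label}", description=""))
    SeqIO.write(records, str(path), "fasta")


def enumerate_pairs(spec: LibrarySpec) -> list[tuple[int, int]]:
    """All barcode index pairs in lexicographic (index1-major) order."""
    return list(itertools.product(range(len(spec.barcodes1)),
                                  range(len(spec.barcodes2))))


def read_used_pairs(path: str | Path, spec: LibrarySpec) -> frozenset[tuple[int, int]]:
    """Read a used-pairs TSV (bc1_name, bc2_name[, sample_name]) to index pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bc1_name", "bc2_name"):
        if col not in df.columns:
            raise LibrarySpecError(f"used-pairs file lacks column {col!r}")
    idx1 = {n: i for i, n in enumerate(spec.barcode1_names)}
    idx2 = {n: i for i, n in enumerate(spec.barcode2_names)}
    pairs = set()
    for _, row in df.iterrows():
        try:
            pairs.add((idx1[row["bc1_name"]], idx2[row["bc2_name"]]))
        except KeyError as exc:
            raise LibrarySpecError(f"unknown barcode name {exc.args[0]!r}") from None
    return frozenset(pairs)
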