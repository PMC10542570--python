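"""Synthetic paired-end libraries and competition trajectories with known truth.

The read simulator emits the exact anatomy the classifier expects: each
template amplicon is

    bc1 + adapter1 + flank_left + allele + flank_right + rc(adapter2) + rc(bc2)

read as mate 1 from the left and mate 2 from the right (reverse
complement), truncated to the configured read length.  Per-read noise
processes, each an independent per-read/per-base probability:

* substitution sequencing error (uniform over the read, random other base);
* a single 1–2 bp insertion or deletion within the mate's flank segment
  (the regime the rescue aligner is built for);
* barcode hopping: one of the two barcodes is swapped for another barcode
  of the same set, creating spurious barcode combinations;
* unknown-allele reads carrying a non-library allele sequence.

Everything is driven by one seeded NumPy generator, so outputs are
byte-identical across runs with the same configuration.  The realized
per-sample allele draws are recorded in a :class:`TruthTable` against which
classifier output can be compared read-for-read.

The trajectory simulator draws replicate fitness values around an offset
power law w̄(t) = (a·t + 1)^b (Gaussian noise on the fitness scale) and
converts them to post-competition frequencies, producing the competition
table consumed by :mod:`dualfreq.fitness`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .fitness import power_law_fitness, predict_post_frequency
from .library_spec import LibrarySpec
from .demux import ReadAnatomy

__all__ = [
    "SampleConfig",
    "SimulationConfig",
    "TruthTable",
    "synthetic_library",
    "simulate_reads",
    "simulate_trajectory",
    "CONTROL_FREQUENCIES",
]

#: Control-grid target frequencies of the focal allele used for benchmarking.
CONTROL_FREQUENCIES = (0.1, 0.45, 0.55, 0.9)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SampleConfig:
    """One sample: its barcode pair, allele mix, and read depth."""

    barcode_pair: tuple[int, int]
    frequencies: dict[str, float]
    depth: int


@dataclass
class SimulationConfig:
    """Noise rates are per read pair (hop, unknown allele, indel per mate)
    or per base (substitution)."""

    spec: LibrarySpec
    samples: list[SampleConfig]
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    barcode_hop_rate: float = 0.0
    unknown_allele_rate: float = 0.0
    read_length: int = 75
    seed: int = 0
    indel_max_size: int = 2
    indel_mates: tuple[str, ...] = ("r1", "r2")

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "barcode_hop_rate",
                     "unknown_allele_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} = {rate} outside [0, 1]")
        for s in self.samples:
            total = sum(s.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {s.barcode_pair} frequencies sum to {total}")
            if s.depth <= 0:
                raise ValueError(f"sample {s.barcode_pair} depth must be > 0")
            unknown = set(s.frequencies) - set(self.spec.alleles)
            if unknown:
                raise ValueError(f"unknown allele label(s) {sorted(unknown)}")
        if not 1 <= self.indel_max_size <= 2:
            raise ValueError("indel_max_size must be 1 or 2")
        if not set(self.indel_mates) <= {"r1", "r2"}:
            raise ValueError("indel_mates entries must be 'r1' or 'r2'")


@dataclass
class TruthTable:
    """Realized ground truth for one simulated library."""

    counts: dict[tuple[int, int, str], int] = field(default_factory=dict)
    unknown_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    total_reads: int = 0
    provenance: pd.DataFrame | None = None

    def depth(self, pair: tuple[int, int]) -> int:
        i1, i2 = pair
        return (sum(n for (a, b, _), n in self.counts.items() if (a, b) == (i1, i2))
                + self.unknown_counts.get((i1, i2), 0))


def synthetic_library(n_bc1: int = 48, n_bc2: int = 48, barcode_length: int = 8,
                      adapter_length: int = 20, flank_length: int = 20,
                      allele_length: int = 6, seed: int = 0) -> LibrarySpec:
    """Generate a plausible library: random barcodes (pairwise Hamming >= 3
    within a set), random constant segments, and two alleles differing at a
    single central position (a biallelic SNP, labeled ``Ara+``/``Ara-`` after
    the classic arabinose-utilization marker)."""
    rng = np.random.default_rng(seed)

    def draw(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    def draw_set(n: int, taken: list[str]) -> list[str]:
        out: list[str] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 100000:
                raise RuntimeError("cannot place barcodes at Hamming >= 3")
            cand = draw(barcode_length)
            if all(sum(a != b for a, b in zip(cand, other)) >= 3
                   for other in out + taken):
                out.append(cand)
        return out

    barcodes1 = draw_set(n_bc1, [])
    barcodes2 = draw_set(n_bc2, barcodes1)
    allele_plus = draw(allele_length)
    snp_pos = allele_length // 2
    alt = rng.choice([b for b in "ACGT" if b != allele_plus[snp_pos]])
    allele_minus = allele_plus[:snp_pos] + str(alt) + allele_plus[snp_pos + 1:]
    return LibrarySpec(
        barcodes1=tuple(barcodes1), barcodes2=tuple(barcodes2),
        adapter1=draw(adapter_length), adapter2=draw(adapter_length),
        flank_left=draw(flank_length), flank_right=draw(flank_length),
        alleles={"Ara+": allele_plus, "Ara-": allele_minus})


def _open_out(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def _mutate_substitutions(read: list[str], positions, rng) -> int:
    for p in positions:
        old = read[p]
        choices = [b for b in "ACGT" if b != old]
        read[p] = choices[rng.integers(3)]
    return len(positions)


def simulate_reads(config: SimulationConfig, r1_path: str | Path,
                   r2_path: str | Path, truth_path: str | Path | None = None,
                   record_provenance: bool = True) -> TruthTable:
    """Write a paired FASTQ library (plain or .gz by extension) plus truth.

    Deterministic per seed.  Returns the :class:`TruthTable` of realized
    allele draws; ``truth_path`` optionally writes its counts as TSV.
    """
    spec = config.spec
    anatomy = ReadAnatomy.from_spec(spec)
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    allele_labels = spec.allele_labels
    allele_len = spec.allele_length
    rc_ad2 = reverse_complement(spec.adapter2)
    truth = TruthTable()
    prov_rows = [] if record_provenance else None
    qual = "I" * L
    r1_path, r2_path = Path(r1_path), Path(r2_path)

    min_amplicon = (anatomy.r1.allele[1] + len(spec.flank_right)
                    + len(spec.adapter2) + spec.barcode2_length)
    if L > min_amplicon:
        raise ValueError(f"read_length {L} exceeds amplicon length {min_amplicon}")
    if L < max(anatomy.r1.min_length, anatomy.r2.min_length):
        raise ValueError("read_length shorter than the read anatomy requires")

    def amplicon(i1: int, i2: int, allele_seq: str) -> str:
        return (spec.barcodes1[i1] + spec.adapter1 + spec.flank_left
                + allele_seq + spec.flank_right + rc_ad2
                + reverse_complement(spec.barcodes2[i2]))

    def random_unknown_allele() -> str:
        while True:
            seq = "".join(rng.choice(_BASES, size=allele_len))
            if seq not in spec.alleles.values():
                return seq

    flank_spans = {"r1": anatomy.r1.flank, "r2": anatomy.r2.flank}

    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        read_index = 0
        for si, sample in enumerate(config.samples):
            i1, i2 = sample.barcode_pair
            labels = list(sample.frequencies)
            probs = np.array([sample.frequencies[l] for l in labels])
            choice_idx = rng.choice(len(labels), size=sample.depth, p=probs)
            unknown_mask = rng.random(sample.depth) < config.unknown_allele_rate
            hop_mask = rng.random(sample.depth) < config.barcode_hop_rate
            n_subs = rng.binomial(L, config.substitution_rate,
                                  size=(sample.depth, 2))
            indel_mask = rng.random((sample.depth, 2)) < config.indel_rate
            # cache the error-free mates per allele for this sample
            base_pairs = {}
            for label in labels:
                amp = amplicon(i1, i2, spec.alleles[label])
                base_pairs[label] = (amp, amp[:L], reverse_complement(amp)[:L])

            for r in range(sample.depth):
                label = labels[choice_idx[r]]
                is_unknown = bool(unknown_mask[r])
                hopped = bool(hop_mask[r])
                truth.total_reads += 1
                if is_unknown:
                    key = (i1, i2)
                    truth.unknown_counts[key] = truth.unknown_counts.get(key, 0) + 1
                else:
                    key3 = (i1, i2, label)
                    truth.counts[key3] = truth.counts.get(key3, 0) + 1

                j1, j2 = i1, i2
                if hopped:
                    side = int(rng.integers(2))
                    if side == 0 and len(spec.barcodes1) > 1:
                        j1 = int((i1 + 1 + rng.integers(len(spec.barcodes1) - 1))
                                 % len(spec.barcodes1))
                    elif side == 1 and len(spec.barcodes2) > 1:
                        j2 = int((i2 + 1 + rng.integers(len(spec.barcodes2) - 1))
                                 % len(spec.barcodes2))
                if is_unknown or hopped or (j1, j2) != (i1, i2):
                    seq = spec.alleles[label] if not is_unknown \
                        else random_unknown_allele()
                    amp = amplicon(j1, j2, seq)
                    mate1, mate2 = amp[:L], reverse_complement(amp)[:L]
                    full1, full2 = amp, reverse_complement(amp)
                else:
                    amp, mate1, mate2 = base_pairs[label]
                    full1, full2 = amp, None  # rc computed lazily below

                indel_desc = []
                mates = [mate1, mate2]
                for m, mate_key in ((0, "r1"), (1, "r2")):
                    if not indel_mask[r, m] or mate_key not in config.indel_mates:
                        continue
                    full = full1 if m == 0 else (
                        full2 if full2 is not None else reverse_complement(amp))
                    fs, fe = flank_spans[mate_key]
                    size = int(rng.integers(1, config.indel_max_size + 1))
                    pos = int(rng.integers(fs, fe - size + 1))
                    if rng.random() < 0.5:
                        ins = "".join(rng.choice(_BASES, size=size))
                        mutated = full[:pos] + ins + full[pos:]
                        indel_desc.append(f"{mate_key}:+{size}@{pos}")
                    else:
                        mutated = full[:pos] + full[pos + size:]
                        indel_desc.append(f"{mate_key}:-{size}@{pos}")
                    mates[m] = mutated[:L]
                mate1, mate2 = mates

                total_subs = 0
                for m in (0, 1):
                    k = int(n_subs[r, m])
                    if k:
                        positions = rng.choice(L, size=k, replace=False)
                        read = list(mates[m])
                        total_subs += _mutate_substitutions(read, positions, rng)
                        mates[m] = "".join(read)
                mate1, mate2 = mates

                rid = f"sim_{si}_{r}"
                f1.write(f"@{rid}\n{mate1}\n+\n{qual}\n")
                f2.write(f"@{rid}\n{mate2}\n+\n{qual}\n")
                if prov_rows is not None:
                    prov_rows.append((rid, i1, i2,
                                      "?" if is_unknown else label,
                                      hopped, j1, j2, total_subs,
                                      ";".join(indel_desc)))
                read_index += 1

    if prov_rows is not None:
        truth.provenance = pd.DataFrame(
            prov_rows, columns=["read_id", "bc1", "bc2", "allele", "hopped",
                                "obs_bc1", "obs_bc2", "n_subs", "indels"])
    if truth_path is not None:
        rows = [(i1, i2, label, n)
                for (i1, i2, label), n in sorted(truth.counts.items())]
        rows += [(i1, i2, "?", n)
                 for (i1, i2), n in sorted(truth.unknown_counts.items())]
        pd.DataFrame(rows, columns=["bc1", "bc2", "allele", "count"]) \
            .to_csv(truth_path, sep="\t", index=False)
    return truth


def control_grid_samples(spec: LibrarySpec, depth: int,
                         frequencies=CONTROL_FREQUENCIES,
                         focal_allele: str = "Ara+") -> list[SampleConfig]:
    """Samples covering every barcode pair, cycling the focal allele through
    the benchmark target frequencies (the loading-control design)."""
    from .library_spec import enumerate_pairs

    labels = spec.allele_labels
    if focal_allele not in labels:
        raise ValueError(f"no allele {focal_allele!r} in the library")
    other = [l for l in labels if l != focal_allele]
    if len(other) != 1:
        raise ValueError("control grid needs a biallelic library")
    samples = []
    for k, pair in enumerate(enumerate_pairs(spec)):
        p = frequencies[k % len(frequencies)]
        samples.append(SampleConfig(
            barcode_pair=pair,
            frequencies={focal_allele: p, other[0]: 1.0 - p},
            depth=depth))
    return samples


def simulate_trajectory(a: float, b: float, time_points, f_E_0: float,
                        T: float, replicate_noise_sd: float = 0.0,
                        n_replicates: int = 8, seed: int = 0):
    """Competition table drawn from w̄(t) = (a·t + 1)^b.

    Per time point and replicate, fitness is the model value plus Gaussian
    noise on the fitness scale (floored just above 0), converted to a
    post-competition frequency by inverting the fitness definition.
    Returns ``(DataFrame, {"a": a, "b": b})``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in time_points:
        w_true = float(power_law_fitness(t, a, b))
        for rep in range(n_replicates):
            w = w_true + (rng.normal(0.0, replicate_noise_sd)
                          if replicate_noise_sd > 0 else 0.0)
            w = max(w, 1e-9)
            f_t = predict_post_frequency(w, f_E_0, T)
            rows.append((float(t), rep, f_E_0, f_t, T))
    df = pd.DataFrame(rows, columns=["time", "replicate", "f_E_0", "f_E_t", "T"])
    return df, {"a": a, "b": b}
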