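"""Allele frequencies and QC summaries from demultiplexed counts.

The frequency of an allele within a sample is its read count divided by the
sample's total genotyped (valid + rescued) reads; one estimate is produced
for every enumerated barcode pair, with zero-coverage pairs reported as
undefined.  QC layers on top:

* error statistics of estimates against known target frequencies, on the
  percent scale, with a nonparametric 95% interval taken from the ECDF of
  observed errors (inverse-ECDF order statistics — no distributional
  assumption);
* classification of the full pair grid into true combinations versus
  spurious ones created by barcode hopping — *double-spurious* pairs combine
  two barcodes that are both used in the library but never together (the
  dangerous class, indistinguishable from real samples by sequence alone)
  and *single-spurious* pairs involve exactly one used barcode;
* the usable-read rate: of the read pairs attributable to the library (two
  individually recognizable barcodes, constant segments within the edit
  budget), the fraction that end up genotyped in a used sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import AlleleCountTable, REJECT_ALLELE
from .library_spec import LibrarySpec, enumerate_pairs

__all__ = [
    "FrequencyEstimate",
    "ErrorSummary",
    "SpuriousReport",
    "compute_frequencies",
    "frequencies_frame",
    "summarize_errors",
    "classify_pairs",
    "usable_read_rate",
    "coverage_rank_frequency",
    "TRUE_COMBINATION",
    "DOUBLE_SPURIOUS",
    "SINGLE_SPURIOUS",
    "UNUSED_BARCODES",
]

TRUE_COMBINATION = "true_combination"
DOUBLE_SPURIOUS = "double_spurious"
SINGLE_SPURIOUS = "single_spurious"
UNUSED_BARCODES = "unused_barcodes"


@dataclass(frozen=True)
class FrequencyEstimate:
    """Per-sample allele frequencies with their denominator."""

    barcode_pair: tuple[int, int]
    frequencies: dict[str, float]
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def compute_frequencies(table: AlleleCountTable,
                        spec: LibrarySpec) -> list[FrequencyEstimate]:
    """One estimate per enumerated pair; frequencies sum to 1 where defined."""
    if not table.check_conservation():
        raise ValueError("count table violates read conservation")
    per_pair: dict[tuple[int, int], dict[str, int]] = {}
    for (i1, i2, label), n in table.counts.items():
        per_pair.setdefault((i1, i2), {})[label] = n
    estimates = []
    for pair in enumerate_pairs(spec):
        counts = per_pair.get(pair, {})
        denom = sum(counts.values())
        freqs = ({label: counts.get(label, 0) / denom
                  for label in spec.allele_labels} if denom else {})
        estimates.append(FrequencyEstimate(pair, freqs, denom))
    return estimates


def frequencies_frame(estimates: list[FrequencyEstimate],
                      spec: LibrarySpec) -> pd.DataFrame:
    """Long-format frame (bc1_name, bc2_name, allele, frequency, denominator)."""
    rows = []
    for est in estimates:
        n1, n2 = spec.pair_name(est.barcode_pair)
        for label in spec.allele_labels:
            rows.append((n1, n2, label,
                         est.frequencies.get(label, np.nan), est.denominator))
    return pd.DataFrame(rows, columns=["bc1_name", "bc2_name", "allele",
                                       "frequency", "denominator"])


@dataclass(frozen=True)
class ErrorSummary:
    """Absolute frequency errors (percent scale) against known targets."""

    errors_pct: np.ndarray
    mean: float
    sd: float
    min: float
    max: float
    ci95: tuple[float, float]
    per_pair: dict[tuple[int, int], float]


def summarize_errors(estimates: list[FrequencyEstimate],
                     targets: dict[tuple[int, int], float],
                     allele: str) -> ErrorSummary:
    """|estimate − target| statistics for the focal allele, in percent.

    Covers every estimate with coverage; each must have a target.  The 95%
    interval is the (2.5th, 97.5th) percentile of the error ECDF using the
    inverse-ECDF (lower order statistic) convention, so both endpoints are
    observed errors.
    """
    per_pair: dict[tuple[int, int], float] = {}
    for est in estimates:
        if not est.defined:
            continue
        if est.barcode_pair not in targets:
            raise KeyError(f"no target frequency for pair {est.barcode_pair}")
        err = abs(est.frequencies.get(allele, 0.0) - targets[est.barcode_pair])
        per_pair[est.barcode_pair] = 100.0 * err
    if not per_pair:
        raise ValueError("no estimates with coverage")
    errors = np.array(list(per_pair.values()))
    lo, hi = np.quantile(errors, [0.025, 0.975], method="inverted_cdf")
    sd = float(errors.std(ddof=1)) if errors.size > 1 else 0.0
    return ErrorSummary(errors_pct=errors, mean=float(errors.mean()), sd=sd,
                        min=float(errors.min()), max=float(errors.max()),
                        ci95=(float(lo), float(hi)), per_pair=per_pair)


@dataclass(frozen=True)
class SpuriousReport:
    """Category and coverage for every pair of the barcode grid."""

    frame: pd.DataFrame  # bc1, bc2, bc1_name, bc2_name, category, coverage
    worst_case_ratio: float

    def coverage(self, category: str) -> pd.Series:
        return self.frame.loc[self.frame["category"] == category, "coverage"]


def classify_pairs(table: AlleleCountTable, spec: LibrarySpec,
                   used_pairs=None) -> SpuriousReport:
    """Label the whole grid and report the true/double-spurious coverage margin.

    ``worst_case_ratio`` = min coverage over true pairs / max coverage over
    double-spurious pairs — how far the weakest real sample sits above the
    strongest hopping artifact (inf when no artifact has coverage).
    """
    used = frozenset(tuple(p) for p in (used_pairs or spec.used_pairs or ()))
    if not used:
        used = frozenset(enumerate_pairs(spec))
    used1 = {i1 for i1, _ in used}
    used2 = {i2 for _, i2 in used}
    per_pair: dict[tuple[int, int], int] = {}
    for (i1, i2, _), n in table.counts.items():
        per_pair[(i1, i2)] = per_pair.get((i1, i2), 0) + n
    rows = []
    for pair in enumerate_pairs(spec):
        i1, i2 = pair
        if pair in used:
            cat = TRUE_COMBINATION
        elif i1 in used1 and i2 in used2:
            cat = DOUBLE_SPURIOUS
        elif i1 in used1 or i2 in used2:
            cat = SINGLE_SPURIOUS
        else:
            cat = UNUSED_BARCODES
        n1, n2 = spec.pair_name(pair)
        rows.append((i1, i2, n1, n2, cat, per_pair.get(pair, 0)))
    frame = pd.DataFrame(rows, columns=["bc1", "bc2", "bc1_name", "bc2_name",
                                        "category", "coverage"])
    true_cov = frame.loc[frame["category"] == TRUE_COMBINATION, "coverage"]
    dbl_cov = frame.loc[frame["category"] == DOUBLE_SPURIOUS, "coverage"]
    if true_cov.empty:
        ratio = float("nan")
    elif dbl_cov.empty or dbl_cov.max() == 0:
        ratio = float("inf")
    else:
        ratio = float(true_cov.min()) / float(dbl_cov.max())
    return SpuriousReport(frame=frame, worst_case_ratio=ratio)


def usable_read_rate(table: AlleleCountTable, used_pairs=None) -> float | None:
    """Usable fraction of library-attributable read pairs.

    Attributable = both barcodes individually recognized and the constant
    segments within the edit budget (i.e. genotyped reads plus
    allele-unrecognized rejects).  Usable = genotyped reads whose pair is in
    ``used_pairs`` (all pairs when not given).  ``None`` when no reads are
    attributable.
    """
    associated = (table.n_valid + table.n_rescued
                  + table.reject_tallies.get(REJECT_ALLELE, 0))
    if associated == 0:
        return None
    if used_pairs is None:
        usable = table.n_valid + table.n_rescued
    else:
        used = frozenset(tuple(p) for p in used_pairs)
        usable = sum(n for (i1, i2, _), n in table.counts.items()
                     if (i1, i2) in used)
    return usable / associated


def coverage_rank_frequency(report: SpuriousReport) -> pd.DataFrame:
    """Coverage sorted descending with 1-based rank (rank-frequency curve)."""
    df = report.frame.sort_values(
        ["coverage", "bc1", "bc2"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def write_spurious_tsv(report: SpuriousReport, path: str | Path) -> None:
    report.frame.to_csv(path, sep="\t", index=False)
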