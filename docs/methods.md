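# Methods

## Library model and read anatomy

A dual-barcoded amplicon library is described by two ordered barcode sets
(up to 48 each, equal length within a set, unique, A/C/G/T only), two
constant adapters, the two constant sequences flanking the polymorphic
position, and a set of equal-length, pairwise-distinct allele sequences.
The amplicon, in read-1 orientation, is

    bc1 · adapter1 · flank_left · allele · flank_right · rc(adapter2) · rc(bc2)

Read 1 covers the molecule from the left; read 2 is its reverse complement
from the right, so in sequencing orientation read 2 begins with barcode 2
and adapter 2 followed by the reverse complement of the right flank.
Segment positions ("anatomy") are explicit configuration derived from the
library's sequence lengths, not hard-coded offsets; read 2 segments are
compared in sequencing orientation against reverse-complemented references,
which is equivalent to reverse-complementing the mate before extraction.
Genotyping uses the read-1 allele span; read 2 contributes barcode 2,
adapter 2 and the right flank to validation.

The on-disk format is a FASTA dialect with role-tagged headers
(`>bc1:NAME`, `>adapter1`, `>flank_left`, `>allele:LABEL`, …). Barcode
index order is file order. This dialect is this package's own definition —
a role prefix is the minimal unambiguous encoding for a single-file library
description.

## Classification ladder

Each read pair receives exactly one verdict, so counts are conserved
(`valid + rescued + rejects = total`):

1. **Barcode lookup** (per mate). Exact hash-table hit wins. With a
   mismatch radius m ≥ 1, the query's Hamming neighbourhood is probed
   (single-base variants against the same hash table for m = 1; a set scan
   for larger m) and the read is assigned only when one barcode is uniquely
   closest within the radius; ties at the minimal distance are
   `barcode_ambiguous`. An `N` in a read matches nothing. The standard
   operating point is m = 0.
2. **Edit budget.** The restricted Damerau–Levenshtein distance (optimal
   string alignment: unit substitutions, insertions, deletions, adjacent
   transpositions, no substring edited twice) is computed for adapter 1 and
   the left flank on read 1 and adapter 2 and the right flank on read 2.
   The default budget of 4 applies to the **sum** over the four segments of
   the pair — the strictest reading of a per-pair threshold; a per-segment
   alternative is exposed (`per_segment_budget`). Distances are computed
   with an early-exit cutoff just above the budget, which cannot change any
   accept/reject decision. The restricted (OSA) variant is used because the
   metric is defined by its four unit operations; the unrestricted variant
   differs only on doubly-edited substrings (e.g. "CA"→"ABC" is 3 under
   OSA, 2 unrestricted).
3. **Genotype.** The allele span must match a library allele exactly;
   tolerant allele matching would bias frequencies toward whichever allele
   sits closer in sequence space.
4. **Rescue.** Reads failing exact genotype match (with barcodes and edit
   budget already validated) are tested for a small indel: the left flank
   is globally aligned (Needleman–Wunsch, match +1 / mismatch −1 / gap −1,
   deterministic diagonal > up > left traceback) to its read window
   extended by `max_shift` (default 3) bases. A terminal overhang of k
   (0 < |k| ≤ max_shift) re-indexes the allele span by k, which is then
   re-queried exactly. When the indel falls in the last base or two of the
   flank the alignment has almost no downstream anchor and the overhang can
   be wrong (a terminal mismatch is cheaper than a gap, or the flank tail
   chases chance matches into the allele); the remaining shifts within
   `max_shift` are therefore probed directly, and the rescue is accepted
   only if all matching shifts agree on a single allele label. A wrong
   shift can only produce a genotype via an exact allele-length k-mer
   collision, which the uniqueness requirement additionally guards; in
   simulated single-indel libraries this procedure genotypes every read
   with zero genotype flips.

Reads shorter than their anatomy are `malformed` (a tally, not a crash).
Base qualities are parsed and ignored — no step of the method uses them.
Gzip input is detected by file extension.

## Frequencies and QC

The frequency of allele *j* in a sample is its count divided by the
sample's genotyped (valid + rescued) reads; every enumerated barcode pair
is reported, zero-coverage pairs as undefined. Error statistics against
known targets are absolute differences on the percent scale; the 95%
interval is the (2.5th, 97.5th) inverse-ECDF quantile, i.e. both endpoints
are observed order statistics, assuming nothing about the error
distribution. The sample standard deviation uses n−1.

Given the set of barcode pairs actually used, the grid partitions into
true combinations, **double-spurious** pairs (both barcodes used, never
together — the class that barcode hopping can silently inflate),
**single-spurious** pairs (exactly one barcode used), and pairs of wholly
unused barcodes. The worst-case margin min(true coverage)/max(double-
spurious coverage) summarizes how far real samples sit above hopping
artifacts. The usable-read rate divides genotyped reads in used pairs by
all library-attributable pairs (both barcodes individually recognized and
segments within the edit budget, i.e. including allele-unrecognized
rejects but excluding barcode and edit-budget rejects).

## Fitness model

Selection coefficients use the per-generation change in log-odds of the
evolved allele with natural logarithms (any consistent base cancels; the
choice is documented rather than consequential), T = log₂(dilution factor)
generations per cycle, and are undefined at frequencies 0 or 1 — such
samples raise errors naming the offending field rather than returning
infinities. The statistic depends only on odds ratios, so counts and
frequencies give identical answers.

Mean fitness over evolutionary time is fitted as the offset power law
w̄(t) = (at+1)^b — the form that clonal-interference plus
diminishing-returns dynamics produce in long-term asexual evolution — by
Levenberg–Marquardt nonlinear least squares (scipy `least_squares`,
method "lm", tolerances 1e-12) on the per-time arithmetic means across
replicates, with confidence bands from the standard error of the mean.
Default start (a, b) = (0.01, 0.1) with a small grid of restarts on
non-convergence; non-convergence is flagged, parameters still reported.
At a = 0 or b = 0 the model is flat and the other parameter is
unidentifiable; fits expose an `identifiable` flag instead of resolving
the ridge. Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·RSS/(n−2). Post-competition frequencies for arbitrary initial
frequencies are predicted by inverting the fitness definition exactly
(f = r/(1+r), r = ŵᵀ·odds₀); prediction and estimation are algebraic
inverses to ~1e-10 over the tested domain, degrading only where f→1
saturates double precision.

## Simulator

The read simulator is the package's study-condition generator, not a
sequencing-machine model. Defaults mirror the validation design the
pipeline is meant for: an 8 × 12 = 96-sample control grid cycling the
focal-allele frequency through {0.1, 0.45, 0.55, 0.9}; 48 × 48 for
capacity checks; 2 × 75 bp reads; a biallelic SNP (labels `Ara+`/`Ara-`
after the classic arabinose marker) centred in a 6-bp allele window with
20-bp adapters and flanks and 8-bp barcodes at pairwise Hamming ≥ 3 within
a set. Noise processes, each independently seeded from one NumPy
generator stream (byte-identical FASTQ per seed):

* per-base substitutions at a configurable rate (1% in accuracy checks —
  a typical short-read error magnitude),
* at most one 1–2 bp indel per mate, restricted to flank segments (the
  regime the rescue aligner addresses and the only place truth-checkable
  shifts arise), with mate and size restrictable for controlled
  experiments,
* barcode hopping: swapping one barcode of a pair for another in-library
  barcode (rate free; no quantitative hopping rate is assumed),
* unknown-allele reads carrying a random non-library allele.

The simulator does **not** model Phred-calibrated quality (qualities are
constant placeholders, and classification ignores them), PCR duplicates,
chimeras, position-dependent error, or wet-lab effects (pipetting,
contamination, amplification bias). Passing accuracy tests therefore
bounds algorithmic plus sampling plus sequencing-substitution error only;
real-library error additionally contains those wet-lab components and is
expected to be larger (percent-scale rather than half-percent-scale mean
absolute error on control grids).

The trajectory simulator draws replicate fitness values around the power
law (Gaussian on the fitness scale, floored above 0) and converts them to
post-competition frequencies through the exact inverse, at the scale of
the motivating experiment (11 time points over 2,000 generations, 8
replicates, 2% initial evolved-strain frequency, T = log₂100).

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use 96-sample grids at
1,000–10,000 reads per sample — enough that binomial sampling error
(≈0.5% at n = 10⁴) is well below the 2% accuracy check — and 200
replications for power-law coverage checks. Determinism: all randomness
flows from explicit seeds; demultiplexing and quantification are
seed-free and exactly reproducible; TSV row order is pair enumeration
(index-1 major) then allele definition order. Edit-distance ties and
alignment traceback ties are broken by fixed rules stated above.

## Known limitations

* Single-locus, biallelic-oriented design; multi-allelic libraries work
  wherever allele sequences are equal-length and distinct, but QC
  summaries focus on one focal allele.
* No single-end mode, UMI handling, quality trimming, or reference
  alignment.
* Rescue searches the left flank only; an indel in the right flank
  (read 2) affects only segment validation, not genotyping.
* The Hamming-radius barcode correction assumes barcode sets designed
  with adequate pairwise distance; with radius ≥ half the minimum set
  distance, ambiguity rejection will discard heavily.
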