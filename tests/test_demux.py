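"""Classification pipeline tests: verdict ladder, rescue, conservation."""

import pandas as pd
import pytest

from dualfreq import DemuxParams, classify_read_pair, demultiplex, rescue_read
from dualfreq.demux import (MALFORMED, REJECT_ALLELE, REJECT_BARCODE_AMBIGUOUS,
                            REJECT_BARCODE_NO_MATCH, REJECT_EDIT_BUDGET,
                            RESCUED, VALID, Demultiplexer, PairedFastqError,
                            ReadAnatomy, read_counts_tsv, write_counts_tsv,
                            write_rejects_tsv)
from dualfreq.simulate import SampleConfig, SimulationConfig, simulate_reads

from conftest import build_pair


def _sub(seq, pos, base=None):
    old = seq[pos]
    new = base or next(b for b in "ACGT" if b != old)
    return seq[:pos] + new + seq[pos + 1:]


def test_error_free_pair_is_valid(small_spec):
    r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
    c = classify_read_pair(r1, r2, small_spec)
    assert c.verdict == VALID
    assert c.barcode_pair == (0, 0)
    assert c.allele == "Ara+"
    assert c.edit_cost == 0


def test_each_barcode_pair_maps_to_itself(small_spec):
    dm = Demultiplexer(small_spec)
    for i1 in range(len(small_spec.barcodes1)):
        for i2 in range(len(small_spec.barcodes2)):
            r1, r2 = build_pair(small_spec, i1, i2, "Ara-")
            c = dm.classify("r", r1, r2)
            assert (c.verdict, c.barcode_pair, c.allele) == (VALID, (i1, i2), "Ara-")


def test_barcode_substitution_rejected_at_mismatch_zero(small_spec):
    r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
    c = classify_read_pair(_sub(r1, 0), r2, small_spec)
    assert c.verdict == REJECT_BARCODE_NO_MATCH
    # with one allowed mismatch the same read is recovered
    c = classify_read_pair(_sub(r1, 0), r2, small_spec,
                           params=DemuxParams(barcode_mismatch=1))
    assert c.verdict == VALID and c.barcode_pair == (0, 0)


def test_ambiguous_barcode_rejected():
    from dualfreq import LibrarySpec
    spec = LibrarySpec(
        barcodes1=("AAAAAA", "AAAATT"), barcodes2=("GGGGGG", "CCCCCC"),
        adapter1="ACGTACGTAC", adapter2="TGCATGCATG",
        flank_left="AACCGGTTAA", flank_right="TTGGCCAATT",
        alleles={"p": "ACGT", "m": "AGGT"})
    r1, r2 = build_pair(spec, 0, 0, "p", read_length=40)
    # mutate barcode1 to be Hamming-1 from both set members
    r1 = "AAAAAT" + r1[6:]  # Hamming 1 from both AAAAAA and AAAATT
    c = classify_read_pair(r1, r2, spec, params=DemuxParams(barcode_mismatch=1))
    assert c.verdict == REJECT_BARCODE_AMBIGUOUS


def test_edit_budget_sum_over_pair(small_spec):
    r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
    a = ReadAnatomy.from_spec(small_spec)
    s1, _ = a.r1.adapter
    s2, _ = a.r2.adapter
    # 3 substitutions in adapter1 (read 1) + 2 in adapter2 (read 2) = 5 > 4
    r1_bad = r1
    for p in (s1, s1 + 3, s1 + 6):
        r1_bad = _sub(r1_bad, p)
    r2_bad = _sub(_sub(r2, s2), s2 + 3)
    c = classify_read_pair(r1_bad, r2_bad, small_spec)
    assert c.verdict == REJECT_EDIT_BUDGET
    # the same reads pass when the budget is applied per segment
    c = classify_read_pair(r1_bad, r2_bad, small_spec,
                           params=DemuxParams(per_segment_budget=True))
    assert c.verdict == VALID
    # and each half alone fits the summed budget
    assert classify_read_pair(r1_bad, r2, small_spec).verdict == VALID
    assert classify_read_pair(r1, r2_bad, small_spec).verdict == VALID


def test_raising_edit_budget_never_loses_reads(small_spec, tmp_path):
    samples = [SampleConfig((i1, i2), {"Ara+": 0.5, "Ara-": 0.5}, 120)
               for i1 in range(2) for i2 in range(2)]
    cfg = SimulationConfig(spec=small_spec, samples=samples,
                           substitution_rate=0.03, seed=9)
    r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    simulate_reads(cfg, r1, r2, record_provenance=False)
    previous = -1
    for budget in range(7):
        table = demultiplex(r1, r2, small_spec,
                            params=DemuxParams(edit_budget=budget))
        genotyped = table.n_valid + table.n_rescued
        assert genotyped >= previous
        assert table.check_conservation()
        previous = genotyped


def test_unrecognized_allele_rejected(small_spec):
    r1, r2 = build_pair(small_spec, 1, 2, "Ara+")
    a = ReadAnatomy.from_spec(small_spec)
    s, e = a.r1.allele
    # scramble the allele into a non-library sequence with 2 substitutions
    bad = _sub(_sub(r1, s), s + 2)
    c = classify_read_pair(bad, r2, small_spec)
    assert c.verdict == REJECT_ALLELE
    assert c.barcode_pair == (1, 2)


def test_short_reads_are_malformed_not_crash(small_spec):
    r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
    assert classify_read_pair(r1[:10], r2, small_spec).verdict == MALFORMED
    assert classify_read_pair(r1, r2[:5], small_spec).verdict == MALFORMED


class TestRescue:

    def test_insertion_in_left_flank_rescued(self, small_spec):
        r1, r2 = build_pair(small_spec, 0, 1, "Ara+")
        a = ReadAnatomy.from_spec(small_spec)
        fs, fe = a.r1.flank
        mid = (fs + fe) // 2
        r1_ins = r1[:mid] + "A" + r1[mid:]
        c = classify_read_pair(r1_ins, r2, small_spec)
        assert c.verdict == RESCUED
        assert c.rescue_shift == +1
        assert c.allele == "Ara+"  # genotype equals the error-free parent

    def test_deletion_in_left_flank_rescued(self, small_spec):
        r1, r2 = build_pair(small_spec, 0, 1, "Ara-")
        a = ReadAnatomy.from_spec(small_spec)
        fs, fe = a.r1.flank
        mid = (fs + fe) // 2
        r1_del = r1[:mid] + r1[mid + 1:]
        c = classify_read_pair(r1_del, r2, small_spec)
        assert c.verdict == RESCUED
        assert c.rescue_shift == -1
        assert c.allele == "Ara-"
        assert rescue_read(r1_del, small_spec) == ("Ara-", -1)

    def test_no_indel_novel_allele_stays_rejected(self, small_spec):
        r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
        a = ReadAnatomy.from_spec(small_spec)
        s, e = a.r1.allele
        novel = "A" * (e - s)
        assert novel not in small_spec.alleles.values()
        r1_bad = r1[:s] + novel + r1[e:]
        c = classify_read_pair(r1_bad, r2, small_spec)
        assert c.verdict == REJECT_ALLELE
        assert rescue_read(r1_bad, small_spec) is None

    def test_shift_beyond_cap_not_rescued(self, small_spec):
        r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
        a = ReadAnatomy.from_spec(small_spec)
        fs, fe = a.r1.flank
        mid = (fs + fe) // 2
        r1_ins = r1[:mid] + "AC" + r1[mid:]  # 2-bp insertion
        c = classify_read_pair(r1_ins, r2, small_spec,
                               params=DemuxParams(max_shift=1))
        assert c.verdict == REJECT_ALLELE
        # with the default cap of 3 the same read is rescued
        c = classify_read_pair(r1_ins, r2, small_spec)
        assert c.verdict == RESCUED and c.rescue_shift == +2

    def test_rescue_disabled(self, small_spec):
        r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
        a = ReadAnatomy.from_spec(small_spec)
        fs, fe = a.r1.flank
        r1_ins = r1[:fs + 2] + "G" + r1[fs + 2:]
        c = classify_read_pair(r1_ins, r2, small_spec,
                               params=DemuxParams(rescue=False))
        assert c.verdict == REJECT_ALLELE


class TestDemultiplex:

    def test_zero_noise_reproduces_truth(self, small_spec, tmp_path):
        samples = [SampleConfig((i1, i2), {"Ara+": 0.3, "Ara-": 0.7}, 250)
                   for i1 in range(2) for i2 in range(3)]
        cfg = SimulationConfig(spec=small_spec, samples=samples, seed=21)
        r1, r2 = tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz"
        truth = simulate_reads(cfg, r1, r2, record_provenance=False)
        table = demultiplex(r1, r2, small_spec)
        assert table.counts == truth.counts
        assert table.reject_tallies == {}
        assert table.total_reads == truth.total_reads
        assert table.check_conservation()

    def test_empty_fastq_pair(self, small_spec, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        r1.write_text("")
        r2.write_text("")
        table = demultiplex(r1, r2, small_spec)
        assert table.total_reads == 0
        assert table.counts == {}

    def test_conservation_under_noise(self, small_spec, tmp_path):
        samples = [SampleConfig((0, 0), {"Ara+": 0.5, "Ara-": 0.5}, 1500)]
        cfg = SimulationConfig(spec=small_spec, samples=samples,
                               substitution_rate=0.01, indel_rate=0.02,
                               unknown_allele_rate=0.05, barcode_hop_rate=0.02,
                               seed=3)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        simulate_reads(cfg, r1, r2, record_provenance=False)
        table = demultiplex(r1, r2, small_spec)
        assert table.total_reads == 1500
        assert table.check_conservation()
        assert sum(table.counts.values()) == table.n_valid + table.n_rescued

    def test_desynchronized_mates_raise(self, small_spec, tmp_path):
        r1, r2 = build_pair(small_spec, 0, 0, "Ara+")
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        p1.write_text(f"@a\n{r1}\n+\n{'I' * len(r1)}\n@b\n{r1}\n+\n{'I' * len(r1)}\n")
        p2.write_text(f"@a\n{r2}\n+\n{'I' * len(r2)}\n")
        with pytest.raises(PairedFastqError, match="different read counts"):
            demultiplex(p1, p2, small_spec)
        p2.write_text(f"@zzz\n{r2}\n+\n{'I' * len(r2)}\n"
                      f"@b\n{r2}\n+\n{'I' * len(r2)}\n")
        with pytest.raises(PairedFastqError, match="desynchronized"):
            demultiplex(p1, p2, small_spec)

    def test_counts_tsv_roundtrip(self, small_spec, tmp_path):
        samples = [SampleConfig((1, 1), {"Ara+": 0.25, "Ara-": 0.75}, 200)]
        cfg = SimulationConfig(spec=small_spec, samples=samples, seed=4)
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        simulate_reads(cfg, r1, r2, record_provenance=False)
        table = demultiplex(r1, r2, small_spec)
        counts_path = tmp_path / "counts.tsv"
        write_counts_tsv(table, small_spec, counts_path)
        write_rejects_tsv(table, tmp_path / "rejects.tsv")
        back = read_counts_tsv(counts_path, small_spec)
        assert back.counts == table.counts
        df = pd.read_csv(counts_path, sep="\t")
        # deterministic order: pair enumeration x allele definition order
        assert len(df) == 12 * 2
        assert df["count"].sum() == 200
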