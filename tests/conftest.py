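import pytest
from Bio.Seq import reverse_complement

from dualfreq import synthetic_library, write_library_spec


@pytest.fixture(scope="session")
def small_spec():
    """4 x 3 barcode library with two SNP alleles."""
    return synthetic_library(n_bc1=4, n_bc2=3, barcode_length=6, seed=11)


@pytest.fixture(scope="session")
def grid_spec():
    """8 x 12 control-grid library."""
    return synthetic_library(n_bc1=8, n_bc2=12, seed=7)


@pytest.fixture()
def small_spec_path(small_spec, tmp_path):
    path = tmp_path / "library.fasta"
    write_library_spec(small_spec, path)
    return path


def build_amplicon(spec, i1, i2, allele_seq):
    """Independent read-pair construction mirroring the library anatomy."""
    return (spec.barcodes1[i1] + spec.adapter1 + spec.flank_left + allele_seq
            + spec.flank_right + reverse_complement(spec.adapter2)
            + reverse_complement(spec.barcodes2[i2]))


def build_pair(spec, i1, i2, label, read_length=75):
    amp = build_amplicon(spec, i1, i2, spec.alleles[label])
    return amp[:read_length], reverse_complement(amp)[:read_length]


@pytest.fixture(scope="session")
def make_pair():
    return build_pair
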