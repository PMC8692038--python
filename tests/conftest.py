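import pytest

from silkforge.simgen import build_gene, simulate_short_reads


@pytest.fixture(scope="session")
def masp4_gene():
    """Standard synthetic MaSp4 gene: 150 aa NTD + 12 x 40 aa repeats +
    100 aa CTD (450 + 12*120 + 300 nt)."""
    return build_gene("MaSp4", n_repeats=12, repeat_len_aa=40, seed=11)


@pytest.fixture(scope="session")
def masp4_short_reads(masp4_gene):
    """Error-free 50x 150 bp reads over the MaSp4 gene."""
    return simulate_short_reads(masp4_gene.cds_nt, coverage=50, read_len=150,
                                err_rate=0.0, seed=2)
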