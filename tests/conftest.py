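import pytest

import gcol
from gcol import fixtures as fx
from gcol.reference import reference_from_fasta


@pytest.fixture(scope="session")
def ref_fa():
    """30 kb, two-contig synthetic reference FASTA."""
    return fx.gen_reference(seed=11, length=30_000, n_contigs=2)


@pytest.fixture(scope="session")
def genome(ref_fa):
    g = reference_from_fasta(ref_fa)
    g.build_index()
    return g


@pytest.fixture(scope="session")
def ref_fa_100k():
    return fx.gen_reference(seed=21, length=100_000)


@pytest.fixture(scope="session")
def genome_100k(ref_fa_100k):
    g = reference_from_fasta(ref_fa_100k)
    g.build_index()
    return g


@pytest.fixture()
def roundtrip(tmp_path):
    """Compress named bytes, decompress, return (restored list, archive path)."""
    def _rt(files, **kw):
        if isinstance(files, tuple):
            files = [files]
        out = tmp_path / "t.gcol"
        ref = kw.pop("reference", None)
        gcol.compress(files, str(out), reference=ref, **kw)
        res = gcol.decompress(str(out), reference=ref)
        return res, str(out)
    return _rt
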