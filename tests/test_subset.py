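"""Region/sample subsetting and downsampling vs. independent text oracles."""
import pytest

import gcol
from gcol import fixtures as fx
from gcol.archive import parse_regions
from gcol.errors import UsageError


def _vcf_header(vcf: bytes) -> bytes:
    end = vcf.index(b"#CHROM")
    return vcf[:end] + vcf[end:].split(b"\n", 1)[0] + b"\n"


def _vcf_body_lines(vcf: bytes):
    return [l for l in vcf.split(b"\n") if l and not l.startswith(b"#")]


@pytest.fixture(scope="module")
def vcf_archive(tmp_path_factory, ref_fa):
    vcf = fx.gen_vcf(ref_fa, seed=81, n_variants=500, n_samples=3)
    out = tmp_path_factory.mktemp("sub") / "v.gcol"
    gcol.compress([("v.vcf", vcf)], str(out), vblock_size=8192)
    return str(out), vcf


def test_region_query_equals_oracle(vcf_archive):
    path, vcf = vcf_archive
    header = _vcf_header(vcf)
    body = _vcf_body_lines(vcf)
    for chrom, lo, hi in (("chr1", 100, 4000), ("chr2", 1, 10**9),
                          ("chr1", 7000, 7000)):
        st = gcol.cat(path, regions=[f"{chrom}:{lo}-{hi}"])
        oracle = [l for l in body
                  if l.split(b"\t")[0].decode() == chrom
                  and lo <= int(l.split(b"\t")[1]) <= hi]
        assert st.results[0].data == header + b"".join(l + b"\n" for l in oracle)


def test_region_whole_file(vcf_archive):
    path, vcf = vcf_archive
    st = gcol.cat(path, regions=["chr1", "chr2"])
    assert st.results[0].data == vcf


def test_nonmatching_vblocks_never_decompressed(vcf_archive):
    path, vcf = vcf_archive
    with gcol.Archive(path) as ar:
        n_vb = len(ar.meta["files"][0]["vblocks"])
        ra = ar.reader.random_access()
    # query restricted to chr2: every vblock holding only chr1 is skipped
    st = gcol.cat(path, regions=["chr2"])
    chr2_vbs = {vb for vb, chrom, _, _ in ra if chrom == "chr2"}
    assert st.vblocks_decompressed == len(chr2_vbs)
    assert st.vblocks_skipped == n_vb - len(chr2_vbs)
    assert st.vblocks_skipped > 0


def test_unknown_chromosome_warns_and_empty(vcf_archive, capsys):
    path, vcf = vcf_archive
    st = gcol.cat(path, regions=["chrX"])
    assert st.results[0].data == _vcf_header(vcf)
    assert "chrX" in capsys.readouterr().err
    assert st.vblocks_decompressed == 0


@pytest.mark.parametrize("bad", ["", ":1-2", "chr1:zz", "chr1:5-2", "chr1:0-4"])
def test_malformed_region_rejected(bad):
    with pytest.raises(UsageError):
        parse_regions([bad])


def test_region_open_end():
    assert parse_regions(["c:10-"]) == [("c", 10, None)]
    assert parse_regions(["c:10"]) == [("c", 10, 10)]
    assert parse_regions(["c"]) == [("c", 1, None)]


def _sample_oracle(vcf: bytes, keep: list[int]) -> bytes:
    out = []
    for l in vcf.split(b"\n")[:-1]:
        if l.startswith(b"##"):
            out.append(l)
            continue
        c = l.split(b"\t")
        out.append(b"\t".join(c[:9] + [c[9 + i] for i in keep]))
    return b"\n".join(out) + b"\n"


def test_sample_subsets_match_oracle(vcf_archive):
    path, vcf = vcf_archive
    for keep, names in (([0], ["S1"]), ([2, 0], ["S3", "S1"]),
                        ([0, 1, 2], ["S1", "S2", "S3"])):
        st = gcol.cat(path, samples=names)
        assert st.results[0].data == _sample_oracle(vcf, keep)


def test_single_sample_column_count(vcf_archive):
    path, _ = vcf_archive
    st = gcol.cat(path, samples=["S2"])
    for line in st.results[0].data.split(b"\n"):
        if line and not line.startswith(b"#"):
            assert len(line.split(b"\t")) == 10  # 8 fixed + FORMAT + 1 sample


def test_unknown_sample_lists_available(vcf_archive):
    path, _ = vcf_archive
    with pytest.raises(UsageError, match="S1, S2, S3"):
        gcol.cat(path, samples=["S9"])


def test_samples_on_non_vcf(tmp_path, ref_fa):
    fq, _ = fx.gen_reads(ref_fa, seed=82, n_reads=20)
    out = tmp_path / "f.gcol"
    gcol.compress([("f.fastq", fq)], str(out))
    with pytest.raises(UsageError, match="VCF"):
        gcol.cat(str(out), samples=["S1"])


def test_downsample_fastq_records(tmp_path, ref_fa):
    fq, _ = fx.gen_reads(ref_fa, seed=83, n_reads=100)
    out = tmp_path / "f.gcol"
    gcol.compress([("f.fastq", fq)], str(out))
    recs = [fq.split(b"\n")[i * 4:(i + 1) * 4] for i in range(100)]
    st = gcol.cat(str(out), downsample=10)
    oracle = b"".join(b"\n".join(r) + b"\n" for i, r in enumerate(recs)
                      if i % 10 == 0)
    assert st.results[0].data == oracle
    assert st.results[0].data.count(b"@SIM") == 10
    # n = 1 -> identity; n > record count -> first record only
    assert gcol.cat(str(out), downsample=1).results[0].data == fq
    big = gcol.cat(str(out), downsample=1000).results[0].data
    assert big == b"\n".join(recs[0]) + b"\n"


def test_downsample_zero_rejected(tmp_path, ref_fa):
    fq, _ = fx.gen_reads(ref_fa, seed=84, n_reads=8)
    out = tmp_path / "f.gcol"
    gcol.compress([("f.fastq", fq)], str(out))
    with pytest.raises(UsageError):
        gcol.cat(str(out), downsample=0)
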