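"""Archive byte format: layout, integrity, random access, binding."""
import hashlib
import struct

import pytest

import gcol
from gcol import fixtures as fx
from gcol.errors import CorruptArchive, Md5Mismatch
from gcol.zfile import SEC_B250, SEC_DICT, SEC_LOCAL, TRAILER_MAGIC


@pytest.fixture()
def sam_archive(tmp_path, ref_fa, genome):
    sam = fx.gen_sam(ref_fa, seed=61, n_reads=900)
    out = tmp_path / "s.gcol"
    gcol.compress([("s.sam", sam)], str(out), reference=genome,
                  vblock_size=32 * 1024)
    return str(out), sam


def test_sections_grouped_by_ascending_vblock(sam_archive):
    path, _ = sam_archive
    with gcol.Archive(path) as ar:
        stream_vbs = [s.vblock for s in ar.reader.sections
                      if s.type in (SEC_B250, SEC_LOCAL)]
        assert stream_vbs == sorted(stream_vbs)
        assert len(set(stream_vbs)) >= 2
        # merged dictionaries come after all per-vblock sections
        first_dict = min(i for i, s in enumerate(ar.reader.sections)
                         if s.type == SEC_DICT)
        last_stream = max(i for i, s in enumerate(ar.reader.sections)
                          if s.type in (SEC_B250, SEC_LOCAL))
        assert first_dict > last_stream


def test_footer_reachable_with_two_seeks(sam_archive):
    path, _ = sam_archive
    with open(path, "rb") as fh:
        fh.seek(-16, 2)                      # seek 1: trailer
        off, = struct.unpack("<Q", fh.read(8))
        assert fh.read(8) == TRAILER_MAGIC
        fh.seek(off)                         # seek 2: footer section
        assert fh.read(2) == b"GS"


def test_md5_stored_and_verified(sam_archive, genome):
    path, sam = sam_archive
    with gcol.Archive(path) as ar:
        assert ar.meta["files"][0]["md5"] == hashlib.md5(sam).hexdigest()
    res = gcol.decompress(path, reference=genome)
    assert res[0].md5_ok


def test_bit_flip_detected(sam_archive, genome, tmp_path):
    path, _ = sam_archive
    blob = bytearray(open(path, "rb").read())
    # flip a byte inside a payload region (past header, before footer)
    blob[len(blob) // 2] ^= 0xFF
    bad = tmp_path / "bad.gcol"
    bad.write_bytes(bytes(blob))
    with pytest.raises((CorruptArchive, Md5Mismatch)):
        gcol.decompress(str(bad), reference=genome)


def test_truncated_archive_detected(sam_archive, genome, tmp_path):
    path, _ = sam_archive
    blob = open(path, "rb").read()
    bad = tmp_path / "trunc.gcol"
    bad.write_bytes(blob[: len(blob) // 2])
    with pytest.raises(CorruptArchive):
        gcol.decompress(str(bad), reference=genome)


def test_not_an_archive(tmp_path):
    p = tmp_path / "x.gcol"
    p.write_bytes(b"definitely not an archive")
    with pytest.raises(CorruptArchive):
        gcol.decompress(str(p))


def test_bind_unbind_three_fastqs(tmp_path, ref_fa):
    files = [("a.fastq", fx.gen_reads(ref_fa, seed=s, n_reads=60)[0])
             for s in (71, 72, 73)]
    files = [(f"f{i}.fastq", data) for i, (_, data) in enumerate(files)]
    out = tmp_path / "bound.gcol"
    gcol.compress(files, str(out))
    res = gcol.decompress(str(out))
    assert len(res) == 3
    for (name, data), r in zip(files, res):
        assert r.name == name and r.data == data
    rows = gcol.list_metadata([str(out)])
    assert len(rows) == 3
    assert {r["md5"] for r in rows} == \
        {hashlib.md5(d).hexdigest() for _, d in files}


def test_unbind_single_file(roundtrip, ref_fa):
    fq, _ = fx.gen_reads(ref_fa, seed=74, n_reads=40)
    res, _ = roundtrip(("only.fastq", fq))
    assert len(res) == 1 and res[0].data == fq


def test_genols_fresh_archive(tmp_path, ref_fa):
    fq, _ = fx.gen_reads(ref_fa, seed=75, n_reads=40)
    out = tmp_path / "a.gcol"
    gcol.compress([("a.fastq", fq)], str(out))
    (row,) = gcol.list_metadata([str(out)])
    assert row["md5"] == hashlib.md5(fq).hexdigest()
    assert row["size"] == len(fq)
    assert row["ratio"] > 1


def test_genols_errors_continue(tmp_path):
    bad = tmp_path / "junk.gcol"
    bad.write_bytes(b"nope")
    rows = gcol.list_metadata([str(bad)])
    assert "error" in rows[0]
    assert gcol.list_metadata([]) == []


def test_merged_dictionaries_globally_unique(sam_archive):
    path, _ = sam_archive
    with gcol.Archive(path) as ar:
        for name, entries in ar.reader.dicts().items():
            assert len(entries) == len(set(entries)), name


def test_ra_index_tight_min_max(tmp_path, ref_fa):
    vcf = fx.gen_vcf(ref_fa, seed=76, n_variants=300, n_samples=1)
    out = tmp_path / "v.gcol"
    gcol.compress([("v.vcf", vcf)], str(out), vblock_size=8192)
    body = [l.split(b"\t") for l in vcf.split(b"\n")
            if l and not l.startswith(b"#")]
    with gcol.Archive(str(out)) as ar:
        ra = ar.reader.random_access()
        vbs = ar.meta["files"][0]["vblocks"]
    # recompute expected per-vblock extents with the same greedy grouping
    # rule the writer uses, then demand exactly one tight entry per
    # (vblock, chrom)
    groups: list[list[list[bytes]]] = []
    cur, size = [], 0
    for fields in body:
        raw_len = len(b"\t".join(fields)) + 1
        cur.append(fields)
        size += raw_len
        if size >= 8192:
            groups.append(cur)
            cur, size = [], 0
    if cur:
        groups.append(cur)
    expected = []
    for vb, group in zip(vbs, groups):
        extent: dict[bytes, list[int]] = {}
        for fields in group:
            chrom, pos = fields[0], int(fields[1])
            lo_hi = extent.setdefault(chrom, [pos, pos])
            lo_hi[0] = min(lo_hi[0], pos)
            lo_hi[1] = max(lo_hi[1], pos)
        for chrom, (lo, hi) in extent.items():
            expected.append([vb, chrom.decode(), lo, hi])
    assert sorted(ra) == sorted(tuple(e) for e in expected)
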