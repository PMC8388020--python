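"""Format detection and per-format segmentation behaviour."""
import pytest

import gcol
from gcol import fixtures as fx
from gcol.errors import FormatError, UsageError
from gcol.segmenters import detect


# -- detection ---------------------------------------------------------------


@pytest.mark.parametrize("name,data,expected", [
    ("x.fastq", b"@r\nAC\n+\nFF\n", "FASTQ"),
    ("x.fq.gz", b"@r\nAC\n+\nFF\n", "FASTQ"),
    ("x.sam", b"@HD\tVN:1.6\n", "SAM"),
    ("x.vcf", b"##fileformat=VCFv4.2\n", "VCF"),
    ("x.fa", b">c\nACGT\n", "FASTA"),
    ("x.bin", b"\x00\x01\x02", "GENERIC"),
])
def test_detect_by_extension(name, data, expected):
    assert detect(name, data).name == expected


@pytest.mark.parametrize("data,expected", [
    (b"##fileformat=VCFv4.2\n#CHROM\t...\n", "VCF"),
    (b"@HD\tVN:1.6\n@SQ\tSN:c\tLN:5\n", "SAM"),
    (b"@read1\nACGT\n+\nFFFF\n", "FASTQ"),
    (b">contig\nACGT\n", "FASTA"),
    (b"\x89PNG\r\n", "GENERIC"),
])
def test_detect_by_sniffing(data, expected):
    assert detect(None, data).name == expected


# -- FASTQ -------------------------------------------------------------------


def test_fastq_uniform_toplevel_dict(tmp_path):
    fq = b"".join(b"@r%d\nACGT\n+\nFFFF\n" % i for i in range(50))
    out = tmp_path / "a.gcol"
    gcol.compress([("u.fastq", fq)], str(out))
    with gcol.Archive(str(out)) as ar:
        top = ar.reader.dicts()["TOPLEVEL"]
        assert len(top) == 1
        # single quality score -> domqual encodes with no exceptions
        import lzma
        (qual_sec,) = ar.reader.find(4, name="QUAL")
        raw = lzma.decompress(ar.reader.payload(qual_sec))
        # byte 0 is the dominant score itself; after it, runs only — no
        # literal exception bytes
        assert raw[0] == ord(b"F") and raw[1:].count(b"F") == 0


@pytest.mark.parametrize("plus", [b"+", b"+read1 desc here"])
def test_fastq_plus_line_forms(roundtrip, plus):
    fq = b"@read1 desc here\nACGT\n" + plus + b"\nFFFF\n"
    res, _ = roundtrip(("p.fastq", fq))
    assert res[0].data == fq


def test_fastq_ragged_record_rejected(tmp_path):
    fq = b"@r\nACGT\n+\nFFF\n"
    with pytest.raises(FormatError, match="read 1"):
        gcol.compress([("bad.fastq", fq)], str(tmp_path / "x.gcol"))


def test_fastq_pair_qname_dedup(tmp_path, ref_fa, genome):
    fq1, fq2, _, _ = fx.gen_reads(ref_fa, seed=41, n_reads=150, paired=True)
    paired = tmp_path / "p.gcol"
    gcol.compress([("r1.fastq", fq1), ("r2.fastq", fq2)], str(paired),
                  reference=genome, pair=True)
    with gcol.Archive(str(paired)) as ar:
        qd = ar.reader.dicts()["QNAME"]
        # mate-2 contributes only the pair-copy snip beyond mate-1 layouts
        assert b"\x04P" in qd
    res = gcol.decompress(str(paired), reference=genome)
    assert res[0].data == fq1 and res[1].data == fq2


def test_fastq_pair_smaller_than_separate(tmp_path, ref_fa, genome):
    fq1, fq2, _, _ = fx.gen_reads(ref_fa, seed=42, n_reads=400, paired=True)
    paired = tmp_path / "p.gcol"
    unpaired = tmp_path / "u.gcol"
    gcol.compress([("r1.fastq", fq1), ("r2.fastq", fq2)], str(paired),
                  reference=genome, pair=True)
    gcol.compress([("r1.fastq", fq1), ("r2.fastq", fq2)], str(unpaired),
                  reference=genome)
    import os
    assert os.path.getsize(str(paired)) < os.path.getsize(str(unpaired))


# -- SAM ---------------------------------------------------------------------


def test_sam_aligned_path_writes_no_gpos(tmp_path, ref_fa, genome):
    sam = fx.gen_sam(ref_fa, seed=43, n_reads=100, aligned_frac=1.0)
    out = tmp_path / "s.gcol"
    gcol.compress([("s.sam", sam)], str(out), reference=genome)
    with gcol.Archive(str(out)) as ar:
        assert not ar.reader.find(4, name="GPOS")
        assert ar.reader.find(4, name="SQBITMAP")


def test_sam_unaligned_records_use_aligner(tmp_path, ref_fa, genome):
    sam = fx.gen_sam(ref_fa, seed=44, n_reads=100, aligned_frac=0.0)
    out = tmp_path / "s.gcol"
    gcol.compress([("s.sam", sam)], str(out), reference=genome)
    with gcol.Archive(str(out)) as ar:
        # RNAME '*' lines: unmapped random reads -> mostly no alignment,
        # but the unaligned path must be the one exercised (no 'A' mode)
        sq = ar.reader.dicts()["SQBITMAP"]
        assert not any(s.startswith(b"\x04SA") for s in sq)
    assert gcol.decompress(str(out), reference=genome)[0].data == sam


def test_sam_cigar_alias_shares_dictionary(tmp_path, ref_fa, genome):
    sam = fx.gen_sam(ref_fa, seed=45, n_reads=200, aligned_frac=1.0)
    out = tmp_path / "s.gcol"
    gcol.compress([("s.sam", sam)], str(out), reference=genome)
    with gcol.Archive(str(out)) as ar:
        dicts = ar.reader.dicts()
        assert "MC:Z" not in dicts          # alias stores no data of its own
        assert "@CIGAR" in dicts
        assert ar.meta["aliases"]["MC:Z"] == "@CIGAR"
        # every MC:Z value repeats a CIGAR value, so the shared dictionary
        # stays no larger than the set of distinct CIGARs
        cigars = {line.split(b"\t")[5] for line in sam.split(b"\n")
                  if line and not line.startswith(b"@")}
        assert len(dicts["@CIGAR"]) <= len(cigars) + 1


def test_sam_too_few_fields(tmp_path):
    with pytest.raises(FormatError, match="11 fields"):
        gcol.compress([("bad.sam", b"r1\t0\tchr\n")], str(tmp_path / "x.gcol"))


# -- VCF ---------------------------------------------------------------------


def test_vcf_gt_matrix_shape(tmp_path, ref_fa):
    vcf = fx.gen_vcf(ref_fa, seed=46, n_variants=40, n_samples=1)
    out = tmp_path / "v.gcol"
    gcol.compress([("v.vcf", vcf)], str(out))
    with gcol.Archive(str(out)) as ar:
        ctxs = ar.reader.vblock_contexts(1)
        m = ctxs["GT"].local.matrix
        assert m.shape == (2, 40)           # diploid single sample


def test_vcf_ref_lookup_with_reference(tmp_path, ref_fa, genome):
    vcf = fx.gen_vcf(ref_fa, seed=47, n_variants=150, n_samples=1)
    with_ref = tmp_path / "r.gcol"
    without = tmp_path / "n.gcol"
    gcol.compress([("v.vcf", vcf)], str(with_ref), reference=genome)
    gcol.compress([("v.vcf", vcf)], str(without))
    with gcol.Archive(str(with_ref)) as ar:
        refs = ar.reader.dicts()["REF"]
        assert any(s.startswith(b"\x04R") for s in refs)
        assert not any(s in (b"A", b"C", b"G", b"T") for s in refs)
    assert gcol.decompress(str(with_ref), reference=genome)[0].data == vcf


def test_vcf_phasing_roundtrip(roundtrip):
    header = (b"##fileformat=VCFv4.2\n"
              b"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n")
    body = (b"c\t10\t.\tA\tT\t50\tPASS\t.\tGT\t0|1\t0/1\n"
            b"c\t20\t.\tA\tT\t50\tPASS\t.\tGT\t1|1\t.\n"
            b"c\t30\t.\tA\tT\t50\tPASS\t.\tGT\t0/0/1\t0|0\n")
    vcf = header + body
    res, _ = roundtrip(("m.vcf", vcf))
    assert res[0].data == vcf


def test_vcf_sample_count_mismatch(tmp_path):
    vcf = (b"##fileformat=VCFv4.2\n"
           b"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
           b"c\t10\t.\tA\tT\t50\tPASS\t.\tGT\t0|1\n")
    with pytest.raises(FormatError, match="columns"):
        gcol.compress([("bad.vcf", vcf)], str(tmp_path / "x.gcol"))


# -- FASTA / generic ---------------------------------------------------------


def test_fasta_wrapping_preserved(roundtrip):
    fa = b">c1\n" + b"ACGTACGTAC\nACGTACG\n\nACG\n" + b">c2 desc\nTTTT\n"
    res, _ = roundtrip(("w.fasta", fa))
    assert res[0].data == fa


def test_generic_text_compresses(tmp_path):
    blob = fx.gen_generic(seed=48, size=200_000, entropy="text")
    out = tmp_path / "g.gcol"
    gcol.compress([("notes.txt", blob)], str(out))
    import os
    assert os.path.getsize(str(out)) < 0.6 * len(blob)
    assert gcol.decompress(str(out))[0].data == blob


def test_generic_random_store_bounded_overhead(tmp_path):
    blob = fx.gen_generic(seed=49, size=100_000, entropy="random")
    out = tmp_path / "g.gcol"
    gcol.compress([("x.bin", blob)], str(out))
    import os
    assert os.path.getsize(str(out)) <= len(blob) + 2048
    with gcol.Archive(str(out)) as ar:
        (sec,) = ar.reader.find(4, name="DATA")
        assert sec.codec == 0  # STORE


def test_mixed_format_bind_rejected(tmp_path):
    with pytest.raises(UsageError, match="mixed"):
        gcol.compress([("a.fastq", b"@r\nA\n+\nF\n"), ("b.fa", b">c\nA\n")],
                      str(tmp_path / "x.gcol"))
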