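"""Reference preprocessing, the k-mer aligner, and sequence encoding."""
import numpy as np
import pytest

import gcol
from gcol import fixtures as fx
from gcol.context import VBlock
from gcol.errors import FormatError
from gcol.reference import (K, ReferenceGenome, encode_seq_aligned,
                            parse_cigar, reference_from_fasta, revcomp)


def test_contig_table_single():
    g = reference_from_fasta(b">chr1\n" + b"ACGT" * 250 + b"\n")
    assert g.contigs == [("chr1", 1000, 0)]


def test_contig_table_offsets():
    g = reference_from_fasta(b">a\n" + b"A" * 100 + b"\n>b\n" + b"C" * 50 + b"\n")
    assert g.contigs == [("a", 100, 0), ("b", 50, 100)]
    assert g.gpos_of("b", 0) == 100
    assert g.contig_of(120)[0] == "b"


def test_duplicate_contigs_rejected():
    with pytest.raises(FormatError):
        reference_from_fasta(b">a\nACGT\n>a\nACGT\n")


def test_empty_fasta_rejected():
    with pytest.raises(FormatError):
        reference_from_fasta(b"")


def test_kmer_index_contains_sampled_positions():
    fa = fx.gen_reference(seed=5, length=10_000)
    g = reference_from_fasta(fa)
    g.build_index()
    # every sampled-position k-mer must list its true gpos among candidates
    seq = g.seq
    misses = 0
    for pos in range(0, len(seq) - K + 1, 4):
        cands = g.lookup_kmer(seq[pos:pos + K])
        if pos not in cands:
            # only acceptable reason: candidate list capped at 8
            assert len(cands) == 8
            misses += 1
    assert misses < 20


def test_align_exact_and_revcomp(genome):
    read = genome.seq[5000:5150]
    got = genome.align(read)
    assert got == (5000, True)
    got_rc = genome.align(revcomp(read))
    assert got_rc == (5000, False)


def test_align_random_read_fails(genome):
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(20):
        read = np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng.integers(0, 4, 150)].tobytes()
        if genome.align(read) is not None:
            hits += 1
    assert hits == 0


def test_aligner_recall_exact_reads(genome_100k, ref_fa_100k):
    fq, truth = fx.gen_reads(ref_fa_100k, seed=31, n_reads=500,
                             mutation_rate=0.0)
    reads = fq.split(b"\n")[1::4]
    correct = 0
    for read, t in zip(reads, truth):
        got = genome_100k.align(read)
        if got is not None and got[0] == t.gpos:
            correct += 1
    assert correct / len(truth) >= 0.99


def test_cigar_parse_and_validation():
    assert parse_cigar(b"4M1I4M") == [(4, ord("M")), (1, ord("I")), (4, ord("M"))]
    with pytest.raises(FormatError):
        parse_cigar(b"4M1B")


def _nonref_bytes(vb):
    return b"".join(vb.contexts["NONREF"].local)


def _bits(vb):
    return np.concatenate(vb.contexts["SQBITMAP"].local)


def test_encode_aligned_exact_match(genome):
    vb = VBlock(1)
    seq = genome.seq[100:110]
    encode_seq_aligned(vb, seq, b"10M", b"chr1", 101, genome)
    assert _bits(vb).all() and _bits(vb).size == 10
    assert _nonref_bytes(vb) == b""


def test_encode_aligned_insertion(genome):
    vb = VBlock(1)
    w = genome.seq[200:208]
    seq = w[:4] + b"G" + w[4:]
    encode_seq_aligned(vb, seq, b"4M1I4M", b"chr1", 201, genome)
    bits = _bits(vb)
    assert bits.size == 8 and bits.all()
    assert _nonref_bytes(vb) == b"G"


def test_encode_aligned_softclip(genome):
    vb = VBlock(1)
    w = genome.seq[300:305]
    seq = b"NNNNN" + w
    encode_seq_aligned(vb, seq, b"5S5M", b"chr1", 301, genome)
    assert _bits(vb).size == 5
    assert _nonref_bytes(vb) == b"NNNNN"


def test_encode_aligned_length_mismatch(genome):
    vb = VBlock(1)
    with pytest.raises(FormatError):
        encode_seq_aligned(vb, b"ACGT", b"10M", b"chr1", 1, genome)


def test_planted_snps_counted(genome):
    from gcol.reference import encode_seq_unaligned
    vb = VBlock(1)
    read = bytearray(genome.seq[1000:1150])
    for off in (30, 90):
        read[off] = ord("A") if read[off] != ord("A") else ord("C")
    encode_seq_unaligned(vb, bytes(read), genome)
    bits = _bits(vb)
    assert int((~bits).sum()) == 2
    assert len(_nonref_bytes(vb)) == 2
    assert set(np.nonzero(~bits)[0].tolist()) == {30, 90}


def test_reference_archive_roundtrip(tmp_path, ref_fa):
    out = tmp_path / "ref.gcol"
    g1 = gcol.make_reference(("r.fa", ref_fa), str(out))
    g2 = gcol.load_reference(str(out))
    assert g2.contigs == g1.contigs
    assert g2.seq == g1.seq
    read = g2.seq[700:850]
    assert g2.align(read) == (700, True)


def test_gpos_mapping_bijective(genome):
    for chrom, length, off in genome.contigs:
        for pos0 in (0, length // 2, length - 1):
            g = genome.gpos_of(chrom, pos0)
            name, clen, coff = genome.contig_of(g)
            assert name == chrom and g - coff == pos0
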