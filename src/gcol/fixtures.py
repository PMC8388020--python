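"""Deterministic synthetic-data generators.

Every input class the test-suite needs — reference FASTA, FASTQ reads
(optionally paired), VCF with genotypes, SAM alignments, generic binary —
is generated here as a pure function of its parameters and a seed; no
downloads.  Read generators also emit a truth table (read index, contig,
0-based gpos, strand, mutated positions) so aligner recall and subsetting
tests close their oracle loop offline.

Default parameters mirror the study conditions of the acceptance checks:
150 bp reads at 0.5% per-base mutation from a 100 kb reference, one
dominant quality score at 85% frequency, VCF genotypes at 2% minor-allele
frequency.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass

import numpy as np

from .reference import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _wrap(seq: bytes, width: int = 60) -> bytes:
    return b"\n".join(seq[i:i + width] for i in range(0, len(seq), width)) + b"\n"


# ---------------------------------------------------------------------------


def gen_reference(seed: int = 1, length: int = 100_000, n_contigs: int = 1,
                  n_islands: int = 0) -> bytes:
    """Uppercase ACGT FASTA, 60-column wrapped, optional N islands."""
    if length < 1000:
        raise ValueError("reference length must be >= 1 kb")
    rng = _rng(seed)
    per = length // n_contigs
    chunks = []
    for c in range(n_contigs):
        n = per if c < n_contigs - 1 else length - per * (n_contigs - 1)
        seq = _BASES[rng.integers(0, 4, n)].tobytes()
        if n_islands:
            arr = bytearray(seq)
            for _ in range(n_islands):
                start = int(rng.integers(0, max(1, n - 20)))
                arr[start:start + 10] = b"N" * 10
            seq = bytes(arr)
        chunks.append(b">chr%d\n" % (c + 1) + _wrap(seq))
    return b"".join(chunks)


@dataclass
class ReadTruth:
    contig: str
    gpos: int            # 0-based global position (contigs concatenated)
    forward: bool
    n_mut: int


def gen_reads(reference_fasta: bytes, seed: int = 2, n_reads: int = 1000,
              read_len: int = 150, mutation_rate: float = 0.005,
              dominant_q: str = "F", dominant_frac: float = 0.85,
              paired: bool = False, insert_size: int = 300,
              name_prefix: bytes = b"SIM"):
    """FASTQ reads sampled from the reference (+ mate file when paired).

    Returns (fastq_bytes, truth) or (fastq1, fastq2, truth1, truth2).
    """
    from .reference import parse_fasta
    entries = parse_fasta(reference_fasta)
    contigs = []
    off = 0
    for name, seq in entries:
        contigs.append((name, seq.upper(), off))
        off += len(seq)
    total = off
    if read_len > min(len(s) for _, s, _ in contigs):
        raise ValueError("read length exceeds contig length")
    rng = _rng(seed)
    quals = np.array([ord(dominant_q)] + [q for q in range(33, 74)
                                          if q != ord(dominant_q)], dtype=np.uint8)

    def _qual() -> bytes:
        pick = rng.random(read_len) < dominant_frac
        alt = quals[rng.integers(1, len(quals), read_len)]
        out = np.where(pick, quals[0], alt).astype(np.uint8)
        return out.tobytes()

    def _one(idx: int, mate: int, pos_hint=None):
        if pos_hint is None:
            ci = int(rng.integers(0, len(contigs)))
            name, seq, coff = contigs[ci]
            start = int(rng.integers(0, len(seq) - read_len + 1))
        else:
            ci, start = pos_hint
            name, seq, coff = contigs[ci]
            start = min(max(start, 0), len(seq) - read_len)
        frag = bytearray(seq[start:start + read_len])
        n_mut = 0
        if mutation_rate > 0:
            hits = np.nonzero(rng.random(read_len) < mutation_rate)[0]
            for h in hits:
                old = frag[h]
                new = int(_BASES[rng.integers(0, 4)])
                if new != old:
                    frag[h] = new
                    n_mut += 1
        fwd = bool(rng.random() < 0.5)
        out_seq = bytes(frag) if fwd else revcomp(bytes(frag))
        title = b"@%s:%d\n" % (name_prefix, idx + 1)  # mates share read names
        rec = title + out_seq + b"\n+\n" + _qual() + b"\n"
        return rec, ReadTruth(name, coff + start, fwd, n_mut), (ci, start)

    recs1, truth1 = [], []
    recs2, truth2 = [], []
    for i in range(n_reads):
        rec, tr, hint = _one(i, 1)
        recs1.append(rec)
        truth1.append(tr)
        if paired:
            rec2, tr2, _ = _one(i, 2, pos_hint=(hint[0], hint[1] + insert_size))
            recs2.append(rec2)
            truth2.append(tr2)
    if paired:
        return b"".join(recs1), b"".join(recs2), truth1, truth2
    return b"".join(recs1), truth1


def truth_table(truth: list[ReadTruth]) -> bytes:
    """TSV sidecar: read_index, contig, gpos, strand, n_mutations."""
    lines = [b"read\tcontig\tgpos\tstrand\tn_mut"]
    for i, t in enumerate(truth):
        lines.append(b"%d\t%s\t%d\t%s\t%d" % (
            i, t.contig.encode(), t.gpos, b"+" if t.forward else b"-", t.n_mut))
    return b"\n".join(lines) + b"\n"


# ---------------------------------------------------------------------------


def gen_vcf(reference_fasta: bytes, seed: int = 3, n_variants: int = 500,
            n_samples: int = 3, maf: float = 0.02, phased_frac: float = 0.5,
            ploidy: int = 2, info: bool = True) -> bytes:
    """Sorted single/multi-sample VCF with REF taken from the reference."""
    from .reference import parse_fasta
    entries = parse_fasta(reference_fasta)
    rng = _rng(seed)
    header = [b"##fileformat=VCFv4.2"]
    for name, seq in entries:
        header.append(b"##contig=<ID=%s,length=%d>" % (name.encode(), len(seq)))
    cols = [b"#CHROM", b"POS", b"ID", b"REF", b"ALT", b"QUAL", b"FILTER", b"INFO"]
    if n_samples:
        cols += [b"FORMAT"] + [b"S%d" % (i + 1) for i in range(n_samples)]
    header.append(b"\t".join(cols))
    body = []
    per = max(1, n_variants // len(entries))
    vid = 0
    for name, seq in entries:
        k = per if name != entries[-1][0] else n_variants - per * (len(entries) - 1)
        k = min(k, len(seq))
        positions = np.sort(rng.choice(len(seq), size=k, replace=False)) + 1
        for pos in positions.tolist():
            vid += 1
            ref_b = seq[pos - 1:pos].upper()
            if ref_b not in (b"A", b"C", b"G", b"T"):
                ref_b = b"A"
            alts = [b for b in (b"A", b"C", b"G", b"T") if b != ref_b]
            alt_b = alts[int(rng.integers(0, 3))]
            fields = [name.encode(), b"%d" % pos, b"rs%d" % (1000 + vid),
                      ref_b, alt_b, b"%d" % int(rng.integers(20, 100)), b"PASS"]
            if info:
                ac = int(rng.integers(0, 2 * n_samples + 1)) if n_samples else 0
                fields.append(b"AC=%d;AN=%d;DB" % (ac, 2 * n_samples))
            else:
                fields.append(b".")
            if n_samples:
                fields.append(b"GT:DP")
                sep = b"|" if rng.random() < phased_frac else b"/"
                for _ in range(n_samples):
                    alleles = (rng.random(ploidy) < maf).astype(int)
                    gt = sep.join(b"%d" % a for a in alleles)
                    fields.append(gt + b":%d" % int(rng.integers(5, 60)))
            body.append(b"\t".join(fields) + b"\n")
    return b"\n".join(header) + b"\n" + b"".join(body)


# ---------------------------------------------------------------------------


def gen_sam(reference_fasta: bytes, seed: int = 4, n_reads: int = 1000,
            read_len: int = 100, aligned_frac: float = 0.9,
            clip_rate: float = 0.1, insert_rate: float = 0.05,
            mutation_rate: float = 0.005, dominant_q: str = "F",
            dominant_frac: float = 0.85, secondary_rate: float = 0.0) -> bytes:
    """SAM text with a mix of aligned, clipped, inserted and unmapped reads."""
    from .reference import parse_fasta
    entries = parse_fasta(reference_fasta)
    rng = _rng(seed)
    header = [b"@HD\tVN:1.6\tSO:coordinate"]
    for name, seq in entries:
        header.append(b"@SQ\tSN:%s\tLN:%d" % (name.encode(), len(seq)))
    header.append(b"@PG\tID:gcolsim\tPN:gcolsim")
    quals = np.array([ord(dominant_q)] + [q for q in range(33, 74)
                                          if q != ord(dominant_q)], dtype=np.uint8)

    def _qual(n) -> bytes:
        pick = rng.random(n) < dominant_frac
        alt = quals[rng.integers(1, len(quals), n)]
        return np.where(pick, quals[0], alt).astype(np.uint8).tobytes()

    recs = []
    for i in range(n_reads):
        qname = b"read:%d" % (i + 1)
        if rng.random() < aligned_frac:
            ci = int(rng.integers(0, len(entries)))
            name, seq = entries[ci]
            seq = seq.upper()
            flag = 0 if rng.random() < 0.5 else 16
            if rng.random() < secondary_rate:
                flag |= 0x100
            start = int(rng.integers(0, len(seq) - read_len + 1))
            frag = bytearray(seq[start:start + read_len])
            hits = np.nonzero(rng.random(read_len) < mutation_rate)[0]
            for h in hits:
                frag[h] = int(_BASES[rng.integers(0, 4)])
            cigar = b"%dM" % read_len
            out = bytes(frag)
            if rng.random() < clip_rate and read_len > 20:
                nclip = int(rng.integers(3, 11))
                clip = _BASES[rng.integers(0, 4, nclip)].tobytes()
                out = clip + bytes(frag)
                cigar = b"%dS%dM" % (nclip, read_len)
            elif rng.random() < insert_rate and read_len > 20:
                at = int(rng.integers(5, read_len - 5))
                ins = _BASES[rng.integers(0, 4, 2)].tobytes()
                out = bytes(frag[:at]) + ins + bytes(frag[at:])
                cigar = b"%dM2I%dM" % (at, read_len - at)
            rec = [qname, b"%d" % flag, name.encode(), b"%d" % (start + 1),
                   b"60", cigar, b"=", b"%d" % (start + 1), b"0",
                   out, _qual(len(out)), b"NM:i:%d" % len(hits),
                   b"MC:Z:" + cigar]
        else:
            n = read_len
            seq_r = _BASES[rng.integers(0, 4, n)].tobytes()
            rec = [qname, b"4", b"*", b"0", b"0", b"*", b"*", b"0", b"0",
                   seq_r, _qual(n)]
        recs.append(b"\t".join(rec) + b"\n")
    return b"\n".join(header) + b"\n" + b"".join(recs)


# ---------------------------------------------------------------------------


def gen_generic(seed: int = 5, size: int = 65536, entropy: str = "random") -> bytes:
    """Binary blob: 'random' (incompressible), 'text', or 'zero'."""
    rng = _rng(seed)
    if entropy == "random":
        return rng.integers(0, 256, size, dtype=np.uint8).tobytes()
    if entropy == "zero":
        return b"\x00" * size
    words = [b"the", b"quick", b"brown", b"genome", b"compressor", b"columnar",
             b"context", b"dictionary", b"reference", b"alignment"]
    out = io.BytesIO()
    while out.tell() < size:
        out.write(words[int(rng.integers(0, len(words)))] + b" ")
        if rng.random() < 0.1:
            out.write(b"\n")
    return out.getvalue()[:size]


def gzip_bytes(data: bytes) -> bytes:
    buf = io.BytesIO()
    with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
        gz.write(data)
    return buf.getvalue()
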