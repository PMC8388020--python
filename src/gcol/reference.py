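"""Reference genome preprocessing and the compression-oriented aligner.

The reference is held as the concatenation of all contigs, addressed by
*gpos* — a 0-based 32-bit global coordinate.  A k-mer index (k=14, every 4th
reference position sampled, at most 8 candidate positions per k-mer) supports
the aligner, which does not look for the biologically correct placement of a
read, only one that compresses well: sampled k-mers of the read and of its
reverse complement vote for implied start positions, and the (gpos, strand)
with the most votes wins.  Alignment is gapless.

Sequence data is encoded into three contexts: SQBITMAP (one bit per
reference-consuming base, 1 = matches the reference), NONREF (mismatching
and non-consuming bases, acgt-coded) and NONREF_X (acgt exception stream).
Unaligned records add GPOS and STRAND ('1' = forward).
"""
from __future__ import annotations

import re

import numpy as np

from . import codecs
from . import context as ctxmod
from .errors import CorruptArchive, FormatError
from .reconstruct import ReconContext, Reconstructor, register_special
from .snips import OP_SPECIAL

K = 14
REF_STRIDE = 4
QUERY_STRIDE = 3
CAP = 8
MIN_VOTE = 2

_COMP = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMP)[::-1]


_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _kmer_codes(base_codes: np.ndarray, positions: np.ndarray, k: int = K
                ) -> tuple[np.ndarray, np.ndarray]:
    """2-bit k-mer codes at *positions*; windows containing non-ACGT dropped."""
    if positions.size == 0:
        return np.zeros(0, dtype=np.uint32), positions
    codes = np.zeros(positions.size, dtype=np.uint32)
    valid = np.ones(positions.size, dtype=bool)
    for j in range(k):
        b = base_codes[positions + j]
        valid &= b != 255
        codes = (codes << 2) | (b & 3).astype(np.uint32)
    return codes[valid], positions[valid]


class ReferenceGenome:
    """Concatenated contigs + k-mer index for the aligner."""

    def __init__(self, contigs: list[tuple[str, int, int]], seq: bytes):
        if not contigs:
            raise FormatError("empty reference")
        if len(seq) >= 2**32:
            raise FormatError("reference exceeds 32-bit gpos space")
        self.contigs = contigs                      # (name, length, gpos_offset)
        self.seq = seq.upper()
        self.by_name = {name: (length, off) for name, length, off in contigs}
        if len(self.by_name) != len(contigs):
            raise FormatError("duplicate contig names in reference")
        self._offsets = np.array([off for _, _, off in contigs], dtype=np.int64)
        self._base_codes = _BASE_LUT[np.frombuffer(self.seq, dtype=np.uint8)]
        self._idx_codes: np.ndarray | None = None
        self._idx_pos: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.seq)

    # -- coordinates --------------------------------------------------------

    def gpos_of(self, chrom: str, pos0: int) -> int:
        try:
            length, off = self.by_name[chrom]
        except KeyError:
            raise FormatError(f"unknown contig {chrom!r}") from None
        if not 0 <= pos0 < length:
            raise FormatError(f"position {pos0 + 1} beyond contig {chrom!r}")
        return off + pos0

    def contig_of(self, gpos: int) -> tuple[str, int, int]:
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        if i < 0 or gpos >= self.contigs[i][2] + self.contigs[i][1]:
            raise CorruptArchive(f"gpos {gpos} outside reference")
        return self.contigs[i]

    def window(self, gpos: int, n: int) -> bytes:
        return self.seq[gpos:gpos + n]

    # -- k-mer index ---------------------------------------------------------

    def build_index(self) -> None:
        n = len(self.seq)
        if n < K:
            self._idx_codes = np.zeros(0, dtype=np.uint32)
            self._idx_pos = np.zeros(0, dtype=np.uint32)
            return
        positions = np.arange(0, n - K + 1, REF_STRIDE, dtype=np.int64)
        codes, positions = _kmer_codes(self._base_codes, positions)
        order = np.lexsort((positions, codes))
        codes, positions = codes[order], positions[order]
        if codes.size:
            # cap candidate lists: keep the CAP smallest gpos per k-mer
            boundary = np.empty(codes.size, dtype=bool)
            boundary[0] = True
            boundary[1:] = codes[1:] != codes[:-1]
            group_start = np.maximum.accumulate(
                np.where(boundary, np.arange(codes.size), 0))
            rank = np.arange(codes.size) - group_start
            keep = rank < CAP
            codes, positions = codes[keep], positions[keep]
        self._idx_codes = codes
        self._idx_pos = positions.astype(np.uint32)

    def set_index(self, codes: np.ndarray, positions: np.ndarray) -> None:
        self._idx_codes = codes
        self._idx_pos = positions

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._idx_codes is None:
            self.build_index()
        return self._idx_codes, self._idx_pos

    def lookup_kmer(self, kmer: bytes) -> list[int]:
        """Candidate gpos list for one k-mer (diagnostics and tests)."""
        codes, _ = _kmer_codes(_BASE_LUT[np.frombuffer(kmer, np.uint8)],
                               np.array([0], dtype=np.int64), len(kmer))
        if codes.size == 0:
            return []
        ic, ip = self.index_arrays()
        lo = int(np.searchsorted(ic, codes[0], "left"))
        hi = int(np.searchsorted(ic, codes[0], "right"))
        return [int(p) for p in ip[lo:hi]]

    # -- aligner -------------------------------------------------------------

    def _vote(self, query: bytes) -> tuple[int, int] | None:
        """Best (votes, gpos) for one orientation, or None."""
        n = len(query)
        if n < K:
            return None
        ic, ip = self.index_arrays()
        if ic.size == 0:
            return None
        base = _BASE_LUT[np.frombuffer(query, dtype=np.uint8)]
        offsets = np.arange(0, n - K + 1, QUERY_STRIDE, dtype=np.int64)
        codes, offsets = _kmer_codes(base, offsets)
        if codes.size == 0:
            return None
        lo = np.searchsorted(ic, codes, "left")
        hi = np.searchsorted(ic, codes, "right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return None
        flat = np.repeat(lo, counts) + (
            np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts))
        implied = ip[flat].astype(np.int64) - np.repeat(offsets, counts)
        implied = implied[(implied >= 0) & (implied + n <= len(self.seq))]
        if implied.size == 0:
            return None
        starts, votes = np.unique(implied, return_counts=True)
        i = int(votes.argmax())       # ties -> smallest gpos (starts ascending)
        return int(votes[i]), int(starts[i])

    def align(self, seq: bytes) -> tuple[int, bool] | None:
        """Compression-oriented gapless placement of *seq*.

        Returns (gpos, is_forward) or None.  Ties prefer forward over
        reverse, then smaller gpos; a best vote count below MIN_VOTE or a
        window that crosses a contig boundary yields no alignment.
        """
        fwd = self._vote(seq)
        rev = self._vote(revcomp(seq))
        if fwd is None and rev is None:
            return None
        best = None
        if fwd is not None:
            best = (fwd[0], True, fwd[1])
        if rev is not None and (best is None or rev[0] > best[0]):
            best = (rev[0], False, rev[1])
        votes, is_fwd, gpos = best
        if votes < MIN_VOTE:
            return None
        name, length, off = self.contig_of(gpos)
        if gpos + len(seq) > off + length:
            return None
        return gpos, is_fwd


# ---------------------------------------------------------------------------
# FASTA parsing (multi-line, CRLF-tolerant) for make-reference


def parse_fasta(data: bytes) -> list[tuple[str, bytes]]:
    entries: list[tuple[str, bytes]] = []
    name: str | None = None
    chunks: list[bytes] = []
    for line in data.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(b">"):
            if name is not None:
                entries.append((name, b"".join(chunks)))
            name = line[1:].split()[0].decode() if len(line) > 1 else ""
            chunks = []
        elif name is None:
            raise FormatError("FASTA does not start with a '>' header")
        else:
            chunks.append(line)
    if name is not None:
        entries.append((name, b"".join(chunks)))
    if not entries:
        raise FormatError("empty FASTA")
    return entries


def reference_from_fasta(data: bytes) -> ReferenceGenome:
    entries = parse_fasta(data)
    contigs = []
    offset = 0
    for name, seq in entries:
        contigs.append((name, len(seq), offset))
        offset += len(seq)
    return ReferenceGenome(contigs, b"".join(s.upper() for _, s in entries))


# ---------------------------------------------------------------------------
# sequence segmentation into SQBITMAP / NONREF / NONREF_X (+ GPOS / STRAND)

_CIGAR_RE = re.compile(rb"(\d+)([MIDNSHP=X])")

# reference/query consumption per SAM v1
_CONSUMES = {
    ord("M"): (True, True), ord("="): (True, True), ord("X"): (True, True),
    ord("I"): (False, True), ord("S"): (False, True),
    ord("D"): (True, False), ord("N"): (True, False),
    ord("H"): (False, False), ord("P"): (False, False),
}


def parse_cigar(cigar: bytes) -> list[tuple[int, int]]:
    ops = [(int(n), op[0]) for n, op in _CIGAR_RE.findall(cigar)]
    if b"".join(b"%d%c" % (n, op) for n, op in ops) != cigar:
        raise FormatError(f"invalid CIGAR {cigar!r}")
    return ops


def cigar_query_len(ops: list[tuple[int, int]]) -> int:
    return sum(n for n, op in ops if _CONSUMES[op][1])


def _seq_ctxs(vb):
    sq = vb.ctx("SQBITMAP", ctxmod.LT_BITS)
    nonref = vb.ctx("NONREF", ctxmod.LT_SEQ, forced_codec=codecs.ACGT)
    return sq, nonref


def _mode_snip(sq, mode: bytes, n: int) -> None:
    sq.seg_snip(b"S" + mode + b"%d" % n, OP_SPECIAL)


def encode_seq_aligned(vb, seq: bytes, cigar: bytes, rname: bytes, pos1: int,
                       ref: ReferenceGenome) -> None:
    """Aligned SAM path: bitmap bit per reference-consuming base."""
    ops = parse_cigar(cigar)
    if cigar_query_len(ops) != len(seq):
        raise FormatError("CIGAR query length differs from sequence length")
    gpos = ref.gpos_of(rname.decode("latin-1"), pos1 - 1)
    name, length, off = ref.contig_of(gpos)
    sq, nonref = _seq_ctxs(vb)
    _mode_snip(sq, b"A", len(seq))
    arr = np.frombuffer(seq, dtype=np.uint8)
    qoff = 0
    roff = 0
    bits: list[np.ndarray] = []
    nr = bytearray()
    for n, op in ops:
        cref, cquery = _CONSUMES[op]
        if cref and cquery:
            if gpos + roff + n > off + length:
                raise FormatError("alignment extends beyond contig")
            w = np.frombuffer(ref.seq[gpos + roff: gpos + roff + n], dtype=np.uint8)
            match = arr[qoff:qoff + n] == w
            bits.append(match)
            if not match.all():
                nr += arr[qoff:qoff + n][~match].tobytes()
            qoff += n
            roff += n
        elif cquery:
            nr += seq[qoff:qoff + n]
            qoff += n
        elif cref:
            roff += n
    sq.add_local(np.concatenate(bits) if bits else np.zeros(0, dtype=bool))
    nonref.add_local(bytes(nr))


def encode_seq_unaligned(vb, seq: bytes, ref: ReferenceGenome | None,
                         pair_gpos: int | None = None,
                         pair_has: bool = False) -> tuple[int | None, bool]:
    """FASTQ / unmapped-SAM path via the aligner.

    Returns (gpos, is_forward) of the placement chosen (gpos None when the
    read did not align or no reference was supplied).  With a paired mate-1
    gpos, GPOS is stored as a signed delta.
    """
    sq, nonref = _seq_ctxs(vb)
    placement = ref.align(seq) if ref is not None else None
    if placement is None:
        _mode_snip(sq, b"N", len(seq))
        nonref.add_local(seq)
        return None, True
    gpos, is_fwd = placement
    gctx = vb.ctx("GPOS", ctxmod.LT_I64)
    sctx = vb.ctx("STRAND", ctxmod.LT_BITS)
    _mode_snip(sq, b"U", len(seq))
    if pair_has and pair_gpos is not None:
        gctx.add_local(gpos - pair_gpos)
    else:
        gctx.add_local(gpos)
    sctx.add_local(np.array([is_fwd], dtype=bool))
    w = ref.window(gpos, len(seq))
    cmp = w if is_fwd else revcomp(w)
    arr = np.frombuffer(seq, dtype=np.uint8)
    match = arr == np.frombuffer(cmp, dtype=np.uint8)
    sq.add_local(match)
    if not match.all():
        nonref.add_local(arr[~match].tobytes())
    return gpos, is_fwd


def encode_seq_verbatim(vb, seq: bytes) -> None:
    """Reference-free path: the whole sequence goes to NONREF (acgt-coded)."""
    sq, nonref = _seq_ctxs(vb)
    _mode_snip(sq, b"N", len(seq))
    nonref.add_local(seq)


def encode_seq_missing(vb) -> None:
    """SAM records with SEQ '*'."""
    sq, _ = _seq_ctxs(vb)
    sq.seg_snip(b"S*", OP_SPECIAL)


# -- decode (special handler 'S') -------------------------------------------


def _nonref(recon: Reconstructor):
    c = recon.ctxs.get("NONREF")
    if c is None or c.local is None:
        raise CorruptArchive("NONREF stream missing")
    return c.local


def _special_seq(recon: Reconstructor, ctx: ReconContext, payload: bytes) -> bytes:
    if payload[:1] == b"*":
        return b"*"
    mode = payload[:1]
    n = int(payload[1:])
    if mode == b"N":
        return _nonref(recon).next_bytes(n)
    ref = recon.reference
    if ref is None:
        raise CorruptArchive("archive requires a reference genome for decompression")
    if mode == b"A":
        return _decode_aligned(recon, ctx, n, ref)
    if mode == b"U":
        return _decode_unaligned(recon, ctx, n, ref)
    raise CorruptArchive(f"unknown sequence mode {mode!r}")


def _decode_aligned(recon: Reconstructor, ctx: ReconContext, n: int,
                    ref: ReferenceGenome) -> bytes:
    cigar = recon.last_text.get("@CIGAR", b"")
    rname = recon.last_text.get("RNAME", b"")
    pos1 = recon.last_int.get("POS", 0)
    ops = parse_cigar(cigar)
    gpos = ref.gpos_of(rname.decode("latin-1"), pos1 - 1)
    nonref = _nonref(recon)
    out = bytearray()
    roff = 0
    for count, op in ops:
        cref, cquery = _CONSUMES[op]
        if cref and cquery:
            bits = ctx.local.next_bits(count)
            w = np.frombuffer(ref.seq[gpos + roff: gpos + roff + count],
                              dtype=np.uint8).copy()
            n_mismatch = int(count - bits.sum())
            if n_mismatch:
                subst = np.frombuffer(nonref.next_bytes(n_mismatch), dtype=np.uint8)
                w[~bits] = subst
            out += w.tobytes()
            roff += count
        elif cquery:
            out += nonref.next_bytes(count)
        elif cref:
            roff += count
    if len(out) != n:
        raise CorruptArchive("sequence length mismatch during reconstruction")
    return bytes(out)


def _decode_unaligned(recon: Reconstructor, ctx: ReconContext, n: int,
                      ref: ReferenceGenome) -> bytes:
    gctx = recon.ctxs.get("GPOS")
    sctx = recon.ctxs.get("STRAND")
    if gctx is None or sctx is None or gctx.local is None or sctx.local is None:
        raise CorruptArchive("GPOS/STRAND streams missing")
    raw = gctx.local.next_int()
    if recon.pair_state is not None:
        mate = recon.pair_state.gpos.get(recon.line_index)
        gpos = mate + raw if mate is not None else raw
    else:
        gpos = raw
    is_fwd = bool(sctx.local.next_bit())
    bits = ctx.local.next_bits(n)
    w = ref.window(gpos, n)
    if len(w) != n:
        raise CorruptArchive("gpos window outside reference")
    cmp = np.frombuffer(w if is_fwd else revcomp(w), dtype=np.uint8).copy()
    n_mismatch = int(n - bits.sum())
    if n_mismatch:
        subst = np.frombuffer(_nonref(recon).next_bytes(n_mismatch), dtype=np.uint8)
        cmp[~bits] = subst
    if recon.collecting_pair is not None:
        recon.collecting_pair.gpos[recon.line_index] = gpos
    return cmp.tobytes()


register_special(b"S", _special_seq)
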