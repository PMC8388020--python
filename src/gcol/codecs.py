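"""Codecs: generic entropy codecs, automatic selection, and the specific
codecs *acgt* (2-bit nucleotide packing), *domqual* (dominant-quality
run-length) and *hapmat* (haplotype-matrix permutation).

Generic codecs are the stock library primitives lzma, bz2 and zlib plus
STORE (identity).  For each context/stream pair the codec is chosen once, by
compressing a <=100 KB sample of the first non-empty buffer with every
generic codec and keeping the best ratio — unless the two best ratios are
within tolerance and the faster codec is at least twice as fast, in which
case speed wins.  Speeds enter the rule through a fixed nominal throughput
table so that the choice (and hence the archive) is reproducible; the
measured sample time is recorded for reporting only.

Specific codecs are "complex" codecs: they transform the data and finish
with a generic pass (lzma).
"""
from __future__ import annotations

import bz2 as _bz2
import lzma as _lzma
import struct
import time
import zlib as _zlib
from dataclasses import dataclass

import numpy as np

from .snips import read_uvarint, write_uvarint

# codec identifiers (one byte in every section header)
STORE = 0
LZMA = 1
BZ2 = 2
ZLIB = 3
ACGT = 4
DOMQUAL = 5
HAPMAT = 6

CODEC_NAMES = {
    STORE: "STORE", LZMA: "LZMA", BZ2: "BZ2", ZLIB: "ZLIB",
    ACGT: "ACGT", DOMQUAL: "DOMQUAL", HAPMAT: "HAPMAT",
}

GENERIC = (LZMA, BZ2, ZLIB, STORE)

#: nominal relative throughput (dimensionless); used by the selection rule in
#: place of wall-clock timing so archives are byte-reproducible.
NOMINAL_SPEED = {LZMA: 1.0, BZ2: 6.0, ZLIB: 30.0, STORE: 1000.0}

SAMPLE_SIZE = 100 * 1024


def generic_encode(codec: int, data: bytes) -> bytes:
    if codec == STORE:
        return data
    if codec == LZMA:
        return _lzma.compress(data, preset=6)
    if codec == BZ2:
        return _bz2.compress(data, 9)
    if codec == ZLIB:
        return _zlib.compress(data, 6)
    raise ValueError(f"not a generic codec: {codec}")


def generic_decode(codec: int, data: bytes) -> bytes:
    try:
        if codec == STORE:
            return data
        if codec == LZMA:
            return _lzma.decompress(data)
        if codec == BZ2:
            return _bz2.decompress(data)
        if codec == ZLIB:
            return _zlib.decompress(data)
    except Exception as exc:  # corrupt payload
        raise CorruptPayload(str(exc)) from exc
    raise ValueError(f"not a generic codec: {codec}")


class CorruptPayload(ValueError):
    pass


@dataclass
class CodecChoice:
    ctx: str
    stream: str               # "b250" | "local"
    codec: int
    sampled_ratio: float
    sampled_time: float       # measured on the sample; informational only

    def as_dict(self) -> dict:
        # measured sample time deliberately omitted: archives must be
        # byte-reproducible, and the decision rule uses nominal speeds
        return {
            "ctx": self.ctx, "stream": self.stream, "codec": self.codec,
            "ratio": round(self.sampled_ratio, 4),
        }


def select_codec(sample: bytes, mode: str = "best") -> tuple[int, float, float]:
    """Pick a generic codec for a stream given a sample of its first buffer.

    Returns (codec, sampled_ratio, sampled_time).  Empty sample -> STORE.
    """
    if not sample:
        return STORE, 1.0, 0.0
    sample = sample[:SAMPLE_SIZE]
    tol = 0.15 if mode == "fast" else 0.05
    results = []
    for codec in GENERIC:
        t0 = time.perf_counter()
        comp = generic_encode(codec, sample)
        dt = time.perf_counter() - t0
        ratio = len(sample) / max(1, len(comp))
        results.append((codec, ratio, dt))
    # best ratio first; ties broken by fixed codec order LZMA>BZ2>ZLIB>STORE
    order = {c: i for i, c in enumerate(GENERIC)}
    results.sort(key=lambda r: (-r[1], order[r[0]]))
    best, second = results[0], results[1]
    if best[1] > 0 and (best[1] - second[1]) / best[1] <= tol:
        if NOMINAL_SPEED[second[0]] >= 2.0 * NOMINAL_SPEED[best[0]]:
            return second[0], second[1], second[2]
    return best[0], best[1], best[2]


# ---------------------------------------------------------------------------
# acgt: 2-bit packing with an exception side-stream (xcgt)

_ACGT_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ACGT_LUT[_b] = _i
_ACGT_INV = np.frombuffer(b"ACGT", dtype=np.uint8)


def acgt_encode(seq: bytes) -> tuple[bytes, bytes]:
    """Pack nucleotides 4-per-byte (A=00 C=01 G=10 T=11, first base in the
    high bits).  Non-ACGT bytes pack as A and are recorded in the *xcgt*
    exception stream as (varint position-delta, original byte) pairs.
    """
    if not seq:
        return b"", b""
    arr = np.frombuffer(seq, dtype=np.uint8)
    codes = _ACGT_LUT[arr]
    bad = np.nonzero(codes == 255)[0]
    xcgt = bytearray()
    if bad.size:
        codes = codes.copy()
        codes[bad] = 0
        prev = 0
        for p in bad.tolist():
            write_uvarint(xcgt, p - prev)
            xcgt.append(arr[p])
            prev = p
    n = len(codes)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    c = codes.reshape(-1, 4)
    packed = (c[:, 0] << 6) | (c[:, 1] << 4) | (c[:, 2] << 2) | c[:, 3]
    return packed.astype(np.uint8).tobytes(), bytes(xcgt)


def acgt_decode(packed: bytes, xcgt: bytes, n: int) -> bytes:
    if n == 0:
        return b""
    p = np.frombuffer(packed, dtype=np.uint8)
    if p.size * 4 < n:
        raise CorruptPayload("acgt: packed stream too short")
    codes = np.empty(p.size * 4, dtype=np.uint8)
    codes[0::4] = p >> 6
    codes[1::4] = (p >> 4) & 3
    codes[2::4] = (p >> 2) & 3
    codes[3::4] = p & 3
    out = _ACGT_INV[codes[:n]].copy()
    pos = 0
    prev = 0
    while pos < len(xcgt):
        delta, pos = read_uvarint(xcgt, pos)
        if pos >= len(xcgt):
            raise CorruptPayload("acgt: truncated exception stream")
        prev += delta
        out[prev] = xcgt[pos]
        pos += 1
    return out.tobytes()


# ---------------------------------------------------------------------------
# domqual: run-length coding around one dominant quality score


def domqual_pick_dominant(quals: list[bytes]) -> int:
    """Most frequent byte in a <=100 KB sample of the quality strings."""
    counts = np.zeros(256, dtype=np.int64)
    seen = 0
    for q in quals:
        take = q[: SAMPLE_SIZE - seen]
        if take:
            counts += np.bincount(np.frombuffer(take, dtype=np.uint8), minlength=256)
            seen += len(take)
        if seen >= SAMPLE_SIZE:
            break
    return int(counts.argmax()) if seen else ord("F")


def domqual_encode(quals: list[bytes], dominant: int) -> bytes:
    """Per string: alternating varint run-lengths of the dominant score and
    single literal bytes copied to the exception stream.  The serialized
    payload is finished with an lzma pass.
    """
    runs = bytearray()
    exceptions = bytearray()
    header = bytearray()
    header.append(dominant & 0xFF)
    write_uvarint(header, len(quals))
    d = dominant
    for q in quals:
        write_uvarint(runs, len(q))
        i = 0
        n = len(q)
        while i < n:
            j = i
            while j < n and q[j] == d:
                j += 1
            write_uvarint(runs, j - i)
            if j < n:
                exceptions.append(q[j])
                j += 1
            i = j
    write_uvarint(header, len(runs))
    return _lzma.compress(bytes(header) + bytes(runs) + bytes(exceptions), preset=6)


def domqual_decode(payload: bytes) -> list[bytes]:
    data = generic_decode(LZMA, payload)
    d = data[0]
    pos = 1
    n_strings, pos = read_uvarint(data, pos)
    runs_len, pos = read_uvarint(data, pos)
    runs_end = pos + runs_len
    runs = data[pos:runs_end]
    exceptions = data[runs_end:]
    out: list[bytes] = []
    rpos = 0
    epos = 0
    dd = bytes([d])
    for _ in range(n_strings):
        strlen, rpos = read_uvarint(runs, rpos)
        s = bytearray()
        while len(s) < strlen:
            run, rpos = read_uvarint(runs, rpos)
            s += dd * run
            if len(s) < strlen:
                if epos >= len(exceptions):
                    raise CorruptPayload("domqual: exception stream exhausted")
                s.append(exceptions[epos])
                epos += 1
        if len(s) != strlen:
            raise CorruptPayload("domqual: run overshoot")
        out.append(bytes(s))
    return out


# ---------------------------------------------------------------------------
# hapmat: greedy nearest-neighbour haplotype reordering + column-major store


def hapmat_order(matrix: np.ndarray) -> np.ndarray:
    """Greedy Hamming-distance ordering of haplotype rows.

    Start from row 0 and repeatedly append the unvisited row closest (by
    Hamming distance) to the last chosen one; ties go to the lowest row
    index.  Deterministic by construction.
    """
    n = matrix.shape[0]
    if n == 0:
        return np.zeros(0, dtype=np.uint32)
    order = np.empty(n, dtype=np.uint32)
    visited = np.zeros(n, dtype=bool)
    order[0] = 0
    visited[0] = True
    last = 0
    big = matrix.shape[1] + 1
    for i in range(1, n):
        dist = np.count_nonzero(matrix != matrix[last], axis=1)
        dist[visited] = big
        last = int(dist.argmin())
        order[i] = last
        visited[last] = True
    return order


def hapmat_encode(matrix: np.ndarray) -> bytes:
    """Encode a rectangular (n_haplotypes x n_variants) uint8 matrix."""
    if matrix.ndim != 2:
        raise ValueError("hapmat requires a rectangular matrix")
    matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
    n_hap, n_var = matrix.shape
    perm = hapmat_order(matrix)
    body = matrix[perm].T.copy()  # column-major emission of permuted rows
    blob = perm.astype("<u4").tobytes() + body.tobytes()
    return struct.pack("<II", n_hap, n_var) + _lzma.compress(blob, preset=6)


def hapmat_decode(payload: bytes) -> np.ndarray:
    if len(payload) < 8:
        raise CorruptPayload("hapmat: short payload")
    n_hap, n_var = struct.unpack_from("<II", payload, 0)
    blob = generic_decode(LZMA, payload[8:])
    if len(blob) != 4 * n_hap + n_hap * n_var:
        raise CorruptPayload("hapmat: size mismatch")
    perm = np.frombuffer(blob[:4 * n_hap], dtype="<u4")
    permuted = np.frombuffer(blob[4 * n_hap:], dtype=np.uint8).reshape(n_var, n_hap).T
    matrix = np.empty((n_hap, n_var), dtype=np.uint8)
    matrix[perm] = permuted
    return matrix
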