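"""Snip encoding: the atomic value of a context dictionary.

A *snip* is a short byte string stored once in a context's dictionary and
referenced by index from the b250 stream.  Most snips are verbatim field
values; a reserved leading byte turns a snip into an instruction for the
reconstructor:

    0x01  LOOKUP_LOCAL  value lives in the context's local buffer
    0x02  DELTA         signed decimal delta vs. an anchor value
    0x03  CONTAINER     structural snip describing a record layout
    0x04  SPECIAL       handled by a registered special handler
    0x05  reserved
    0x06  escape byte

Verbatim payloads may contain any byte; bytes 0x00-0x06 are escaped so that
the leading-byte opcode convention and the 0x00-terminated dictionary
serialization stay unambiguous.
"""
from __future__ import annotations

from typing import Iterable, Iterator

OP_VERBATIM = 0x00
OP_LOOKUP_LOCAL = 0x01
OP_DELTA = 0x02
OP_CONTAINER = 0x03
OP_SPECIAL = 0x04
OP_RESERVED = 0x05
ESCAPE = 0x06

_NEEDS_ESCAPE = frozenset(range(0x00, ESCAPE + 1))


def _escape(payload: bytes) -> bytes:
    if not payload or min(payload) > ESCAPE:
        return payload
    out = bytearray()
    for b in payload:
        if b in _NEEDS_ESCAPE:
            out.append(ESCAPE)
            out.append(0x40 | b)
        else:
            out.append(b)
    return bytes(out)


def _unescape(data: bytes) -> bytes:
    if ESCAPE not in data:
        return data
    out = bytearray()
    it = iter(data)
    for b in it:
        if b == ESCAPE:
            out.append(next(it) & 0x3F)
        else:
            out.append(b)
    return bytes(out)


def encode_snip(payload: bytes, opcode: int = OP_VERBATIM) -> bytes:
    """Serialize (opcode, payload) to the stored dictionary form."""
    if opcode == OP_VERBATIM:
        return _escape(payload)
    if not OP_LOOKUP_LOCAL <= opcode <= OP_RESERVED:
        raise ValueError(f"invalid snip opcode {opcode:#x}")
    return bytes([opcode]) + _escape(payload)


def decode_snip(stored: bytes) -> tuple[int, bytes]:
    """Inverse of :func:`encode_snip`."""
    if stored and OP_LOOKUP_LOCAL <= stored[0] <= OP_RESERVED:
        return stored[0], _unescape(stored[1:])
    return OP_VERBATIM, _unescape(stored)


def pack_dict(stored_snips: Iterable[bytes]) -> bytes:
    """Serialize a dictionary: stored snips, each 0x00-terminated."""
    return b"".join(s + b"\x00" for s in stored_snips)


def unpack_dict(blob: bytes) -> list[bytes]:
    if not blob:
        return []
    parts = blob.split(b"\x00")
    if parts[-1] != b"":
        raise ValueError("corrupt dictionary: missing terminator")
    return parts[:-1]


# ---------------------------------------------------------------------------
# LEB128 varints: the b250 stream is a sequence of unsigned varint dictionary
# indices; signed values (xcgt deltas never need it, but kept for generality)
# use zigzag.

def write_uvarint(out: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("uvarint requires value >= 0")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            out.append(b | 0x80)
        else:
            out.append(b)
            return


def uvarint(value: int) -> bytes:
    out = bytearray()
    write_uvarint(out, value)
    return bytes(out)


def read_uvarint(data: bytes, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if pos >= len(data):
            raise ValueError("truncated varint")
        b = data[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


def encode_b250(indices: Iterable[int]) -> bytes:
    out = bytearray()
    for i in indices:
        write_uvarint(out, i)
    return bytes(out)


def decode_b250(data: bytes) -> list[int]:
    out: list[int] = []
    pos = 0
    n = len(data)
    while pos < n:
        v, pos = read_uvarint(data, pos)
        out.append(v)
    return out


def iter_b250(data: bytes) -> Iterator[int]:
    pos = 0
    n = len(data)
    while pos < n:
        v, pos = read_uvarint(data, pos)
        yield v
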