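"""Archive byte format.

An archive is a sequence of self-describing *sections*:

    FILE_HEADER  archive-level JSON (version, data type)
    TXT_HEADER   verbatim-compressed source-file header (one per bound file)
    B250/LOCAL   per-vblock, per-context compressed streams
    DICT         global merged dictionaries (written after all vblocks)
    RANDOM_ACCESS  (vblock, chrom, min_pos, max_pos) index entries
    REFERENCE    embedded reference genome sections (optional)
    FOOTER       JSON offsets of every section + per-file metadata

All multi-byte integers are little-endian.  The file opens with magic
``GCOL1`` and ends with a 16-byte trailer (footer offset + end magic), so
any single section is reachable with at most two seeks.  Every section
carries a CRC32, which distinguishes a corrupt archive from an MD5 mismatch
of correctly-decoded data.
"""
from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass

import numpy as np

from . import codecs
from . import context as ctxmod
from .errors import CorruptArchive
from .reconstruct import LocalStream, ReconContext
from .snips import _escape, _unescape, decode_b250, encode_b250, pack_dict, unpack_dict

MAGIC = b"GCOL1\x01"
TRAILER_MAGIC = b"GCOLFTR1"

SEC_FILE_HEADER = 1
SEC_TXT_HEADER = 2
SEC_B250 = 3
SEC_LOCAL = 4
SEC_DICT = 5
SEC_RANDOM_ACCESS = 6
SEC_REFERENCE = 7
SEC_FOOTER = 8

_HDR = struct.Struct("<2sBI16sBBQQI")  # magic, type, vblock, name, codec, ltype, unc, comp, crc
_SEC_MAGIC = b"GS"


@dataclass
class SectionInfo:
    offset: int
    type: int
    vblock: int
    name: str
    codec: int
    ltype: int
    unc_len: int
    comp_len: int


class ArchiveWriter:
    def __init__(self, fh):
        self.fh = fh
        self.offset = 0
        self.sections: list[SectionInfo] = []
        self._write(MAGIC)

    def _write(self, data: bytes) -> None:
        self.fh.write(data)
        self.offset += len(data)

    def add_section(self, sec_type: int, vblock: int, name: str, codec: int,
                    ltype: int, unc_len: int, payload: bytes) -> None:
        name_b = name.encode()
        if len(name_b) > 16:
            raise ValueError(f"section name too long: {name}")
        info = SectionInfo(self.offset, sec_type, vblock, name, codec, ltype,
                           unc_len, len(payload))
        hdr = _HDR.pack(_SEC_MAGIC, sec_type, vblock, name_b.ljust(16, b"\x00"),
                        codec, ltype, unc_len, len(payload),
                        zlib.crc32(payload) & 0xFFFFFFFF)
        self._write(hdr)
        self._write(payload)
        self.sections.append(info)

    def finish(self, meta: dict) -> None:
        meta = dict(meta)
        meta["sections"] = [
            [s.offset, s.type, s.vblock, s.name, s.codec, s.ltype, s.unc_len, s.comp_len]
            for s in self.sections
        ]
        payload = zlib.compress(json.dumps(meta, separators=(",", ":")).encode(), 6)
        footer_off = self.offset
        hdr = _HDR.pack(_SEC_MAGIC, SEC_FOOTER, 0, b"FOOTER".ljust(16, b"\x00"),
                        codecs.ZLIB, 0, 0, len(payload),
                        zlib.crc32(payload) & 0xFFFFFFFF)
        self._write(hdr)
        self._write(payload)
        self._write(struct.pack("<Q", footer_off) + TRAILER_MAGIC)


# ---------------------------------------------------------------------------
# local buffer serialization (encode side)


def serialize_local(ctx: ctxmod.Context) -> bytes:
    lt = ctx.ltype
    if lt in (ctxmod.LT_TEXT, ctxmod.LT_NONE):
        return b"".join(_escape(s) + b"\x00" for s in ctx.local)
    if lt == ctxmod.LT_U8:
        return bytes(ctx.local)
    if lt == ctxmod.LT_U32:
        return np.array(ctx.local, dtype="<u4").tobytes()
    if lt == ctxmod.LT_I64:
        return np.array(ctx.local, dtype="<i8").tobytes()
    if lt == ctxmod.LT_BITS:
        bits = (np.concatenate(ctx.local) if ctx.local
                else np.zeros(0, dtype=bool))
        return struct.pack("<Q", bits.size) + np.packbits(
            bits.astype(np.uint8), bitorder="little").tobytes()
    if lt in (ctxmod.LT_SEQ, ctxmod.LT_BYTES):
        return b"".join(ctx.local)
    if lt == ctxmod.LT_ID:
        return b"".join(struct.pack("<IB", n, w) for n, w in ctx.local)
    raise ValueError(f"unknown ltype {lt}")


def deserialize_local(name: str, ltype: int, raw: bytes) -> LocalStream:
    if ltype in (ctxmod.LT_TEXT, ctxmod.LT_NONE):
        return LocalStream(ctxmod.LT_TEXT, items=[_unescape(p) for p in unpack_dict(raw)])
    if ltype == ctxmod.LT_U8:
        return LocalStream(ltype, ints=np.frombuffer(raw, dtype=np.uint8).astype(np.int64))
    if ltype == ctxmod.LT_U32:
        return LocalStream(ltype, ints=np.frombuffer(raw, dtype="<u4").astype(np.int64))
    if ltype == ctxmod.LT_I64:
        return LocalStream(ltype, ints=np.frombuffer(raw, dtype="<i8").astype(np.int64))
    if ltype == ctxmod.LT_BITS:
        if len(raw) < 8:
            raise CorruptArchive(f"context {name}: truncated bitmap")
        (count,) = struct.unpack_from("<Q", raw, 0)
        bits = np.unpackbits(np.frombuffer(raw[8:], dtype=np.uint8),
                             bitorder="little")
        if bits.size < count:
            raise CorruptArchive(f"context {name}: bitmap too short")
        return LocalStream(ltype, bits=bits[:count].astype(bool))
    if ltype in (ctxmod.LT_SEQ, ctxmod.LT_BYTES):
        return LocalStream(ltype, data=raw)
    if ltype == ctxmod.LT_ID:
        n = len(raw) // 5
        items = [struct.unpack_from("<IB", raw, 5 * i) for i in range(n)]
        return LocalStream(ltype, items=items)
    raise CorruptArchive(f"context {name}: unknown local type {ltype}")


# ---------------------------------------------------------------------------
# per-vblock section emission with codec selection


def _choose(zstate: ctxmod.ZState, name: str, stream: str, sample: bytes) -> int:
    key = (name, stream)
    choice = zstate.codec_choices.get(key)
    if choice is None:
        codec, ratio, dt = codecs.select_codec(sample, zstate.mode)
        choice = codecs.CodecChoice(name, stream, codec, ratio, dt)
        zstate.codec_choices[key] = choice
    return choice.codec


def write_vblock_sections(writer: ArchiveWriter, vb: ctxmod.VBlock,
                          zstate: ctxmod.ZState) -> None:
    """Compress and append one vblock's B250/LOCAL sections (merge order)."""
    for name in sorted(vb.contexts):
        ctx = vb.contexts[name]
        if ctx.b250:
            raw = encode_b250(ctx.b250)
            codec = _choose(zstate, name, "b250", raw)
            writer.add_section(SEC_B250, vb.vblock_id, name, codec, 0,
                               len(raw), codecs.generic_encode(codec, raw))
        if not ctx.local:
            continue
        forced = ctx.forced_codec
        if forced == codecs.ACGT:
            raw = serialize_local(ctx)
            packed, xcgt = codecs.acgt_encode(raw)
            writer.add_section(SEC_LOCAL, vb.vblock_id, name, codecs.ACGT,
                               ctx.ltype, len(raw),
                               codecs.generic_encode(codecs.LZMA, packed))
            writer.add_section(SEC_LOCAL, vb.vblock_id, name + "_X",
                               codecs.LZMA, ctxmod.LT_BYTES, len(xcgt),
                               codecs.generic_encode(codecs.LZMA, xcgt))
            zstate.codec_choices.setdefault(
                (name, "local"),
                codecs.CodecChoice(name, "local", codecs.ACGT, 0.0, 0.0))
        elif forced == codecs.DOMQUAL:
            dom = zstate.domqual_dominant.get(name)
            if dom is None:
                dom = codecs.domqual_pick_dominant(ctx.local)
                zstate.domqual_dominant[name] = dom
            unc = sum(len(q) + 1 for q in ctx.local)
            payload = codecs.domqual_encode(ctx.local, dom)
            writer.add_section(SEC_LOCAL, vb.vblock_id, name, codecs.DOMQUAL,
                               ctx.ltype, unc, payload)
            zstate.codec_choices.setdefault(
                (name, "local"),
                codecs.CodecChoice(name, "local", codecs.DOMQUAL, 0.0, 0.0))
        elif forced == codecs.HAPMAT:
            (matrix,) = ctx.local
            payload = codecs.hapmat_encode(matrix)
            writer.add_section(SEC_LOCAL, vb.vblock_id, name, codecs.HAPMAT,
                               ctxmod.LT_BYTES, int(matrix.size), payload)
            zstate.codec_choices.setdefault(
                (name, "local"),
                codecs.CodecChoice(name, "local", codecs.HAPMAT, 0.0, 0.0))
        else:
            raw = serialize_local(ctx)
            codec = forced if forced is not None else _choose(
                zstate, name, "local", raw)
            writer.add_section(SEC_LOCAL, vb.vblock_id, name, codec,
                               ctx.ltype, len(raw),
                               codecs.generic_encode(codec, raw))


def write_dict_sections(writer: ArchiveWriter, zstate: ctxmod.ZState) -> None:
    for name in sorted(zstate.contexts):
        z = zstate.contexts[name]
        if not z.dict_list:
            continue
        raw = pack_dict(z.dict_list)
        writer.add_section(SEC_DICT, 0, name, codecs.LZMA, 0, len(raw),
                           codecs.generic_encode(codecs.LZMA, raw))


# ---------------------------------------------------------------------------
# reader


class ArchiveReader:
    def __init__(self, fh):
        self.fh = fh
        head = fh.read(len(MAGIC))
        if head != MAGIC:
            raise CorruptArchive("not a gcol archive (bad magic)")
        fh.seek(-16, 2)
        trailer = fh.read(16)
        if trailer[8:] != TRAILER_MAGIC:
            raise CorruptArchive("archive trailer missing or damaged")
        (footer_off,) = struct.unpack("<Q", trailer[:8])
        fh.seek(footer_off)
        sec_type, _, _, _, _, payload = self._read_section_at(footer_off)
        if sec_type != SEC_FOOTER:
            raise CorruptArchive("footer not found at recorded offset")
        try:
            self.meta = json.loads(zlib.decompress(payload).decode())
        except Exception as exc:
            raise CorruptArchive(f"footer unreadable: {exc}") from exc
        self.sections = [
            SectionInfo(o, t, vb, nm, cod, lt, unc, comp)
            for o, t, vb, nm, cod, lt, unc, comp in self.meta["sections"]
        ]
        self._dicts: dict[str, list[bytes]] | None = None

    def _read_section_at(self, offset: int):
        self.fh.seek(offset)
        hdr = self.fh.read(_HDR.size)
        if len(hdr) != _HDR.size:
            raise CorruptArchive("truncated section header")
        magic, sec_type, vblock, name, codec, ltype, unc, comp, crc = _HDR.unpack(hdr)
        if magic != _SEC_MAGIC:
            raise CorruptArchive("bad section magic")
        payload = self.fh.read(comp)
        if len(payload) != comp:
            raise CorruptArchive("truncated section payload")
        clean_name = name.rstrip(b"\x00").decode()
        if zlib.crc32(payload) & 0xFFFFFFFF != crc:
            raise CorruptArchive(f"CRC mismatch in section {clean_name!r}")
        return sec_type, vblock, clean_name, codec, ltype, payload

    def payload(self, info: SectionInfo) -> bytes:
        _, _, _, _, _, payload = self._read_section_at(info.offset)
        return payload

    def find(self, sec_type: int, vblock: int | None = None,
             name: str | None = None) -> list[SectionInfo]:
        return [s for s in self.sections
                if s.type == sec_type
                and (vblock is None or s.vblock == vblock)
                and (name is None or s.name == name)]

    # -- high-level loads ----------------------------------------------------

    def dicts(self) -> dict[str, list[bytes]]:
        if self._dicts is None:
            self._dicts = {}
            for info in self.find(SEC_DICT):
                raw = codecs.generic_decode(info.codec, self.payload(info))
                self._dicts[info.name] = unpack_dict(raw)
        return self._dicts

    def random_access(self) -> list[tuple[int, str, int, int]]:
        out = []
        for info in self.find(SEC_RANDOM_ACCESS):
            doc = json.loads(codecs.generic_decode(info.codec, self.payload(info)))
            out.extend((vb, chrom, lo, hi) for vb, chrom, lo, hi in doc)
        return out

    def vblock_contexts(self, vblock_id: int) -> dict[str, ReconContext]:
        """Decode one vblock's sections into reconstruction-ready contexts."""
        dicts = self.dicts()
        raw_local: dict[str, tuple[int, int, bytes, int]] = {}
        b250s: dict[str, list[int]] = {}
        for info in self.sections:
            if info.vblock != vblock_id:
                continue
            if info.type == SEC_B250:
                raw = codecs.generic_decode(info.codec, self.payload(info))
                b250s[info.name] = decode_b250(raw)
            elif info.type == SEC_LOCAL:
                raw_local[info.name] = (info.codec, info.ltype,
                                        self.payload(info), info.unc_len)
        locals_: dict[str, LocalStream] = {}
        for name, (codec, ltype, payload, unc_len) in raw_local.items():
            if codec == codecs.ACGT:
                packed = codecs.generic_decode(codecs.LZMA, payload)
                xinfo = raw_local.get(name + "_X")
                xcgt = (codecs.generic_decode(xinfo[0], xinfo[2])
                        if xinfo is not None else b"")
                seq = codecs.acgt_decode(packed, xcgt, unc_len)
                locals_[name] = LocalStream(ltype, data=seq)
            elif codec == codecs.DOMQUAL:
                locals_[name] = LocalStream(ctxmod.LT_TEXT,
                                            items=codecs.domqual_decode(payload))
            elif codec == codecs.HAPMAT:
                locals_[name] = LocalStream(ctxmod.LT_BYTES,
                                            matrix=codecs.hapmat_decode(payload))
            else:
                raw = codecs.generic_decode(codec, payload)
                locals_[name] = deserialize_local(name, ltype, raw)
        out: dict[str, ReconContext] = {}
        for name in set(b250s) | set(locals_):
            loc = locals_.get(name)
            out[name] = ReconContext(
                name,
                dicts.get(name, []),
                b250s.get(name, []),
                loc,
                loc.ltype if loc is not None else ctxmod.LT_NONE,
            )
        return out
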