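"""Contexts, vblocks and the clone/segment/merge lifecycle.

A *context* is the per-data-component store: a dictionary of unique snips, a
b250 stream of dictionary indices (one per occurrence) and a typed *local*
byte buffer for non-dictionary data (numbers, sequences, bitmaps, codec
payloads).  Each vblock owns a private set of contexts; after segmentation
the vblock dictionaries are merged into the global archive state in
vblock-id order, which fixes global snip numbering deterministically whether
segmentation ran serially or in parallel.

Singleton rule: a verbatim snip occurring exactly once in the merging vblock
and absent from the global dictionary is not merged; its payload moves to the
context's local buffer and its b250 entry becomes a LOOKUP_LOCAL snip.  This
keeps one-off values (typically read names) out of the dictionaries.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .container import Container
from .snips import (
    OP_CONTAINER,
    OP_DELTA,
    OP_LOOKUP_LOCAL,
    OP_SPECIAL,
    OP_VERBATIM,
    decode_snip,
    encode_snip,
)

# local buffer types; the byte value is written in the section header
LT_NONE = 0      # dictionary-only context (may acquire singleton text)
LT_TEXT = 1      # 0x00-terminated escaped strings
LT_U8 = 2
LT_U32 = 3
LT_I64 = 4
LT_BITS = 5      # bit stream (bitmaps: SQBITMAP, STRAND)
LT_SEQ = 6       # raw nucleotide bytes (acgt codec input)
LT_ID = 7        # (uint32 number, uint8 decimal width) pairs from seg_id
LT_BYTES = 8     # opaque bytes (generic segmenter, codec payloads)

LOOKUP_SNIP = encode_snip(b"", OP_LOOKUP_LOCAL)


class Context:
    """A vblock-local context."""

    __slots__ = (
        "name", "dict_list", "dict_map", "counts", "b250", "local",
        "ltype", "alias_of", "forced_codec", "cloned_len",
    )

    def __init__(self, name: str, ltype: int = LT_NONE):
        if len(name.encode()) > 16:
            raise ValueError(f"context name too long: {name!r}")
        self.name = name
        self.dict_list: list[bytes] = []
        self.dict_map: dict[bytes, int] = {}
        self.counts: list[int] = []
        self.b250: list[int] = []
        self.local: list = []          # items; type per ltype
        self.ltype = ltype
        self.alias_of: str | None = None
        self.forced_codec: int | None = None
        self.cloned_len = 0

    # -- dictionary path ----------------------------------------------------

    def seg_stored(self, stored: bytes) -> int:
        """Append one occurrence of a stored-form snip; return its index."""
        idx = self.dict_map.get(stored)
        if idx is None:
            idx = len(self.dict_list)
            self.dict_list.append(stored)
            self.dict_map[stored] = idx
            self.counts.append(0)
        self.counts[idx] += 1
        self.b250.append(idx)
        return idx

    def seg_snip(self, payload: bytes, opcode: int = OP_VERBATIM) -> int:
        return self.seg_stored(encode_snip(payload, opcode))

    def seg_container(self, c: Container) -> int:
        return self.seg_stored(c.to_snip())

    # -- local path ---------------------------------------------------------

    def set_ltype(self, ltype: int) -> None:
        if self.ltype == LT_NONE:
            self.ltype = ltype
        elif self.ltype != ltype:
            raise ValueError(f"context {self.name}: local type conflict")

    def add_local(self, item) -> None:
        self.local.append(item)


# ---------------------------------------------------------------------------
# framework built-in segmentation algorithms


def seg_snip(ctx: Context, payload: bytes) -> int:
    """Place *payload* directly in its context (option 1)."""
    return ctx.seg_snip(payload)


def seg_container(ctx: Context, c: Container) -> int:
    return ctx.seg_container(c)


def seg_pos(ctx: Context, pos_text: bytes, anchor: int) -> int:
    """Store position data as a delta vs. the previous value (anchor).

    Returns the new anchor.  Non-numeric input falls back to a verbatim snip
    and leaves the anchor unchanged.
    """
    if not _is_int(pos_text):
        ctx.seg_snip(pos_text)
        return anchor
    pos = int(pos_text)
    ctx.seg_snip(b"\x00%d" % (pos - anchor), OP_DELTA)
    return pos


_ID_RE = re.compile(rb"\A([^\W\d_]+)(\d+)\Z", re.ASCII)


def seg_id(ctx: Context, id_text: bytes) -> None:
    """Split IDs like b'rs23424' into a dictionary prefix and a local number.

    The numeric part is stored as (uint32, decimal-width) in the context's
    local buffer so leading zeros round-trip; anything that is not
    prefix+digits (or whose number exceeds 2**32-1) is stored verbatim.
    """
    m = _ID_RE.match(id_text)
    if m:
        number = int(m.group(2))
        width = len(m.group(2))
        if number < 2**32 and width < 256:
            ctx.set_ltype(LT_ID)
            ctx.seg_snip(b"I" + m.group(1), OP_SPECIAL)
            ctx.add_local((number, width))
            return
    ctx.seg_snip(id_text)


def seg_delta_vs(ctx: Context, value_text: bytes, base_ctx: str, base_value: int) -> None:
    """Store *value* as a DELTA snip naming another context as its base."""
    if not _is_int(value_text):
        ctx.seg_snip(value_text)
        return
    delta = int(value_text) - base_value
    ctx.seg_snip(base_ctx.encode() + b"\x00%d" % delta, OP_DELTA)


def _is_int(text: bytes) -> bool:
    if text.startswith(b"-"):
        text = text[1:]
    return text.isdigit()


# ---------------------------------------------------------------------------
# vblock


class VBlock:
    """A bounded chunk of whole input lines with its private context set."""

    def __init__(self, vblock_id: int):
        self.vblock_id = vblock_id
        self.contexts: dict[str, Context] = {}
        self.aliases: dict[str, str] = {}
        self.line_count = 0
        self.txt_len = 0
        self.ra: dict[str, list[int]] = {}  # chrom -> [min_pos, max_pos]

    def ctx(self, name: str, ltype: int = LT_NONE, forced_codec: int | None = None,
            alias_of: str | None = None) -> Context:
        if alias_of is not None:
            self.aliases[name] = alias_of
            return self.ctx(alias_of)
        name = self.aliases.get(name, name)
        c = self.contexts.get(name)
        if c is None:
            c = Context(name, ltype)
            self.contexts[name] = c
        elif ltype != LT_NONE:
            c.set_ltype(ltype)
        if forced_codec is not None:
            c.forced_codec = forced_codec
        return c

    def note_position(self, chrom: bytes, pos: int) -> None:
        """Random-access index hook: record (chrom, pos) of the current line."""
        key = chrom.decode("latin-1")
        entry = self.ra.get(key)
        if entry is None:
            self.ra[key] = [pos, pos]
        else:
            if pos < entry[0]:
                entry[0] = pos
            if pos > entry[1]:
                entry[1] = pos


# ---------------------------------------------------------------------------
# global (archive) context state


class ZContext:
    __slots__ = ("name", "dict_list", "dict_map", "counts", "ltype", "forced_codec")

    def __init__(self, name: str):
        self.name = name
        self.dict_list: list[bytes] = []
        self.dict_map: dict[bytes, int] = {}
        self.counts: list[int] = []
        self.ltype = LT_NONE
        self.forced_codec: int | None = None


class ZState:
    """Per-archive global state: merged dictionaries and codec choices."""

    def __init__(self, mode: str = "best"):
        self.contexts: dict[str, ZContext] = {}
        self.aliases: dict[str, str] = {}
        self.codec_choices: dict[tuple[str, str], "object"] = {}
        self.domqual_dominant: dict[str, int] = {}
        self.mode = mode
        self.merged_vblocks = 0

    def zctx(self, name: str) -> ZContext:
        z = self.contexts.get(name)
        if z is None:
            z = ZContext(name)
            self.contexts[name] = z
        return z


def clone_contexts(zstate: ZState, vb: VBlock) -> None:
    """Pre-populate a new vblock's contexts from the global dictionaries.

    Cloning is an optimisation: merge-time remapping assigns the final global
    indices regardless of how current the clone was, which is what makes
    parallel segmentation byte-identical to serial.
    """
    for name, z in zstate.contexts.items():
        c = Context(name, z.ltype)
        c.dict_list = list(z.dict_list)
        c.dict_map = dict(z.dict_map)
        c.counts = [0] * len(z.dict_list)
        c.cloned_len = len(z.dict_list)
        c.forced_codec = z.forced_codec
        vb.contexts[name] = c
    vb.aliases.update(zstate.aliases)


def _singleton_eligible(ctx: Context, stored: bytes) -> bool:
    # only verbatim snips of dictionary-only contexts move to local
    if ctx.ltype not in (LT_NONE, LT_TEXT):
        return False
    return not (stored and OP_LOOKUP_LOCAL <= stored[0] <= 0x05)


def merge_contexts(zstate: ZState, vb: VBlock) -> None:
    """Merge a vblock's dictionaries into the global state (vblock-id order).

    Rewrites the vblock's b250 streams to global numbering and applies the
    singleton rule.  Must be called exactly once per vblock, in ascending
    vblock_id order.
    """
    for name in sorted(vb.contexts):
        ctx = vb.contexts[name]
        z = zstate.zctx(name)
        if ctx.ltype != LT_NONE:
            if z.ltype == LT_NONE:
                z.ltype = ctx.ltype
            elif z.ltype != ctx.ltype:
                raise ValueError(f"context {name}: local type changed between vblocks")
        if ctx.forced_codec is not None:
            z.forced_codec = ctx.forced_codec

        if not ctx.b250 and len(ctx.dict_list) == ctx.cloned_len:
            continue

        mapping: dict[int, int] = {}
        singles: set[int] = set()
        for i, stored in enumerate(ctx.dict_list):
            g = z.dict_map.get(stored)
            if g is not None:
                mapping[i] = g
                z.counts[g] += ctx.counts[i]
                continue
            if ctx.counts[i] == 1 and _singleton_eligible(ctx, stored):
                singles.add(i)
                continue
            g = len(z.dict_list)
            z.dict_list.append(stored)
            z.dict_map[stored] = g
            z.counts.append(ctx.counts[i])
            mapping[i] = g

        if singles:
            ctx.set_ltype(LT_TEXT)
            lookup_g = z.dict_map.get(LOOKUP_SNIP)
            if lookup_g is None:
                lookup_g = len(z.dict_list)
                z.dict_list.append(LOOKUP_SNIP)
                z.dict_map[LOOKUP_SNIP] = lookup_g
                z.counts.append(0)
            new_b250 = []
            for idx in ctx.b250:
                if idx in singles:
                    _, payload = decode_snip(ctx.dict_list[idx])
                    ctx.local.append(payload)
                    z.counts[lookup_g] += 1
                    new_b250.append(lookup_g)
                else:
                    new_b250.append(mapping[idx])
            ctx.b250 = new_b250
        elif mapping:
            ctx.b250 = [mapping[i] for i in ctx.b250]
    zstate.aliases.update(vb.aliases)
    zstate.merged_vblocks += 1
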