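"""Segmenter base class, registry and shared field helpers.

A segmenter decomposes one logical line of its format into contexts and
registers the TOPLEVEL container describing the layout.  Segmenters are
looked up by file extension, then by content sniffing; unrecognised input
falls through to the Generic segmenter.  New formats are added by
registering a segmenter class — the reconstructor needs no changes.
"""
from __future__ import annotations

import re
from typing import Iterator

from .. import context as ctxmod
from ..container import Container, item
from ..context import seg_pos
from ..errors import FormatError

REGISTRY: dict[str, type] = {}
_EXT_MAP: dict[str, str] = {}


def register(cls: type) -> type:
    REGISTRY[cls.name] = cls
    for ext in getattr(cls, "extensions", ()):
        _EXT_MAP[ext] = cls.name
    return cls


def by_name(name: str) -> type:
    try:
        return REGISTRY[name]
    except KeyError:
        raise FormatError(f"unknown data type {name!r}") from None


def detect(filename: str | None, data: bytes) -> type:
    """Extension first, then magic-byte / structure sniffing, else Generic."""
    if filename:
        low = filename.lower()
        if low.endswith(".gz"):
            low = low[:-3]
        for ext, name in _EXT_MAP.items():
            if low.endswith(ext):
                return REGISTRY[name]
    head = data[:65536]
    for name in ("VCF", "SAM", "FASTQ", "FASTA"):
        cls = REGISTRY.get(name)
        if cls is not None and cls.sniff(head):
            return cls
    return REGISTRY["GENERIC"]


class Segmenter:
    """One instance segments one file (or, in parallel mode, one vblock)."""

    name = "?"
    extensions: tuple[str, ...] = ()
    record_lines = 1          # textual lines per logical line
    ra_ctxs: tuple[str, str] | None = None   # (chrom ctx, pos ctx) for indexing
    text_based = True

    def __init__(self, zstate, opts):
        self.zstate = zstate
        self.opts = opts
        self.ref = opts.reference
        self.anchors: dict[str, int] = {}

    @classmethod
    def sniff(cls, head: bytes) -> bool:
        return False

    @classmethod
    def split_header(cls, data: bytes) -> tuple[bytes, bytes]:
        return b"", data

    def parse_header(self, header: bytes) -> None:
        pass

    def iter_records(self, body: bytes) -> Iterator[bytes]:
        if not body:
            return
        start = 0
        n = len(body)
        while start < n:
            end = start
            for _ in range(self.record_lines):
                nl = body.find(b"\n", end)
                if nl < 0:
                    raise FormatError(
                        f"{self.name}: truncated record at byte {start}")
                end = nl + 1
            yield body[start:end]
            start = end

    def begin_vblock(self, vb) -> None:
        self.anchors = {}

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        raise NotImplementedError

    def end_vblock(self, vb) -> None:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# shared helper: tokenised IDs (read names) — sub-segmentation of a field
# into alternating literal/numeric items inside a container

_TOKEN_SPLIT = re.compile(b"([:/_ ])")
_MAX_TOKENS = 12


def seg_tokenized(vb, ctx_name: str, text: bytes, anchors: dict[str, int],
                  prefix: str = "Q") -> None:
    """Split ``text`` on [:/_ ] into per-token contexts inside a container.

    Numeric tokens (no leading zeros) are stored as deltas vs. the previous
    line, which collapses incrementing read names to a single snip.
    """
    parts = _TOKEN_SPLIT.split(text)
    tokens = parts[0::2]
    seps = parts[1::2]
    if len(tokens) > _MAX_TOKENS:
        vb.ctx(ctx_name).seg_snip(text)
        return
    items = []
    for i, tok in enumerate(tokens):
        tname = f"{prefix}{i}"
        sep = seps[i] if i < len(seps) else b""
        tctx = vb.ctx(tname)
        if tok.isdigit() and (tok == b"0" or not tok.startswith(b"0")) \
                and len(tok) < 19:
            anchors[tname] = seg_pos(tctx, tok, anchors.get(tname, 0))
        else:
            tctx.seg_snip(tok)
        items.append(item(tname, sep=sep))
    vb.ctx(ctx_name).seg_container(Container(tuple(items)))
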