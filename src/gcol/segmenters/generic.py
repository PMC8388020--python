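"""Generic segmenter for unrecognised (possibly binary) input.

Trivial by design: the entire vblock is placed in the local buffer of a
single context and the codec is auto-selected.
"""
from __future__ import annotations

from .. import context as ctxmod
from ..container import Container, item
from .base import Segmenter, register


@register
class GenericSegmenter(Segmenter):
    name = "GENERIC"
    extensions = ()
    text_based = False

    def iter_records(self, body: bytes):
        # one "line" per vblock-sized chunk; no newline semantics
        size = self.opts.vblock_size
        for start in range(0, len(body), size):
            yield body[start:start + size]
        if not body:
            return

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        vb.ctx("DATA", ctxmod.LT_BYTES).add_local(record)

    def end_vblock(self, vb) -> None:
        vb.ctx("TOPLEVEL").seg_container(
            Container((item("DATA"),), repeats=vb.line_count))
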