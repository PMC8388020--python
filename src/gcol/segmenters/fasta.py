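"""FASTA segmenter.

Description lines become dictionary snips; sequence lines go to a local
buffer compressed with the acgt codec (non-nucleotide characters, e.g. in
protein FASTA, ride the exception stream and still round-trip).  Per-line
lengths are recorded so the original wrapping is reproduced exactly.
"""
from __future__ import annotations

from .. import codecs
from .. import context as ctxmod
from ..container import Container, item
from ..errors import CorruptArchive
from ..reconstruct import register_special
from ..snips import OP_SPECIAL
from .base import Segmenter, register


@register
class FastaSegmenter(Segmenter):
    name = "FASTA"
    extensions = (".fasta", ".fa", ".fna", ".faa")

    @classmethod
    def sniff(cls, head: bytes) -> bool:
        return head.startswith(b">")

    def seg_record(self, vb, record: bytes, line_index: int) -> None:
        line = record[:-1]
        ctx = vb.ctx("FLINE")
        if line.startswith(b">") or not line:
            ctx.seg_snip(line)
        else:
            ctx.seg_snip(b"F%d" % len(line), OP_SPECIAL)
            vb.ctx("SEQ", ctxmod.LT_SEQ, forced_codec=codecs.ACGT).add_local(line)

    def end_vblock(self, vb) -> None:
        vb.ctx("TOPLEVEL").seg_container(
            Container((item("FLINE", sep=b"\n"),), repeats=vb.line_count))


def _special_fasta_seq(recon, ctx, payload):
    c = recon.ctxs.get("SEQ")
    if c is None or c.local is None:
        raise CorruptArchive("FASTA sequence stream missing")
    return c.local.next_bytes(int(payload))


register_special(b"F", _special_fasta_seq)
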